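# cenloop

Spike-in calibrated ChIP-seq quantification and pericentromeric contact-map
analytics for budding yeast.

`cenloop` is built for studies of cohesin-mediated DNA loops around yeast
centromeres — the setting in which the Scc2-bound, loop-extrusion-competent
pool of cohesin reshapes chromosome folding.  It implements, as a tested and
reusable library, the full quantitative stack such a study needs:

* **Spike-in calibration.**  For a ChIP experiment where *S. cerevisiae*
  cells are mixed with *C. glabrata* spike-in cells, the occupancy ratio

  ```
  OR = (ChIP_Scer x input_Cgla) / (input_Scer x ChIP_Cgla)
  ```

  quantifies absolute target-genome occupancy against the spike-in, and the
  normalization factor `NF = OR_treated / OR_control` puts samples on a
  common scale.  The binned ChIP vector is rescaled so its genome-wide total
  is `1,500,000 x NF` (input to 1,500,000) and the per-100-bp-bin ratio of
  the two is the normalized fold-enrichment (nFE) track, on which peaks are
  called at the threshold nFE >= 2.
* **Site analytics.**  nFE quantification at cohesin binding sites, Scc2-level
  quartile grouping (Q1–Q4), Scc2/Scc1 (or Pds5/Scc1) ratio statistics
  normalized to the wild-type median, aggregate profiles with 95% confidence
  bands, sorted heatmap matrices, and centromere-distance annotation with
  the 5-kb pericentromeric exclusion.
* **Contact-map analytics** on plain-text COO cis matrices: iterative-
  correction balancing, per-arm expected profiles, contact-vs-distance decay
  curves P(s) with their log-log derivative, diamond-window insulation
  scores (5/10-kb windows) with boundary calls, a simplified HICCUPS-style
  loop caller (donut / lower-left / horizontal / vertical local backgrounds,
  Poisson tests, BH-FDR 0.1, 2.5-kb merge), observed/expected pile-ups (APA)
  with the central 3x3 enrichment score, and loop / anchor-site
  classification relative to centromeres and cohesin sites.
* **Gene context.**  CEN-/TEL-oriented labeling of the genes flanking each
  cohesin site (relative to transcription direction and the centromere) and
  two-sided Mann-Whitney U comparisons of gene length and RNA-polymerase
  occupancy between anchor and non-anchor sites.
* **Synthetic data.**  A first-class generator producing dual-genome ChIP
  counts (multinomial) and cis contact maps (Poisson over a power-law decay
  with injected loop dots, domains and centromere insulation), plus two
  encoded study conditions — `wt_like` (dense ~20-kb cohesin–cohesin loops,
  little Scc2 at arm sites) and `wpl1_eco1_like` (sparse centromere-anchored
  loops of mean ~67 kb, Scc2/Scc1 fold 2.53) — with exported ground truth,
  so every stage is testable without sequencing data.

## Worked example

Run both encoded study conditions end to end (simulate → calibrate →
sites → contacts → genes) and contrast them:

```python
from cenloop.pipeline import RunConfig, run_pipeline

wt  = run_pipeline(RunConfig(scenario="wt_like", seed=1))
mut = run_pipeline(RunConfig(scenario="wpl1_eco1_like", seed=1))

for name, r in (("wt_like", wt), ("wpl1_eco1_like", mut)):
    c = r["contacts"]
    print(f"{name}: {c['n_loops']} loops, "
          f"mean CEN-loop length {c['mean_cen_loop_length']/1e3:.1f} kb, "
          f"APA central score {c['apa_central_score']:.2f}, "
          f"Scc2/Scc1 median fold {r['sites']['scc2_scc1_median_fold']:.2f}")
fold = mut["contacts"]["mean_cen_loop_length"] / wt["contacts"]["mean_cen_loop_length"]
print(f"CEN-loop length fold (mutant/wt): {fold:.2f}")
print(f"anchor sites flagged in mutant: {mut['contacts']['anchor_sites']} "
      f"(truth agreement {mut['contacts']['anchor_truth_agreement_pct']:.0f}%)")
print(f"CEN-oriented gene length p (anchor vs non-anchor): "
      f"{mut['genes']['cen_oriented']['length_p']:.2e}")
```

which prints:

```
wt_like: 118 loops, mean CEN-loop length 16.5 kb, APA central score 2.42, Scc2/Scc1 median fold 1.00
wpl1_eco1_like: 24 loops, mean CEN-loop length 65.5 kb, APA central score 3.90, Scc2/Scc1 median fold 2.62
CEN-loop length fold (mutant/wt): 3.97
anchor sites flagged in mutant: 24 (truth agreement 100%)
CEN-oriented gene length p (anchor vs non-anchor): 7.72e-14
```

Reading these numbers: the wild-type-like condition yields many short loops
between adjacent cohesin sites, while the mutant-like condition yields few,
long centromere-anchored loops (~4-fold longer on average), recovered with
anchors matching the generator's manifest exactly.  The calibrated Scc2/Scc1
ratio fold (2.62 recovered vs 2.53 injected) quantifies the increased
Scc2–cohesin affinity, and the gene test shows that centromere-oriented
genes at loop-anchor sites are significantly longer — the loop-extrusion
barrier signature.

The same stages are available from the shell:

```bash
cenloop run --scenario wpl1_eco1_like --seed 1 --outdir out/
cenloop simulate --scenario wt_like --seed 1 --outdir sim/
cenloop peaks --nfe out/nfe_scc2.bedgraph --chrom-sizes sim/genome.chrom.sizes --out peaks.bed
cenloop contacts loops --matrix out/matrix_chrI.coo --cen 110000 --out loops.bedpe
cenloop compare out_wt/report.json out_mut/report.json
```

## Layout

```
src/cenloop/
  core.py         intervals, annotations, binned tracks, contact maps
  io.py           chrom.sizes / BED / GFF3 / bedGraph / COO / BEDPE
  simulate.py     synthetic ChIP + contact generators, study scenarios
  calibration.py  OR, NF, nFE tracks, peak calling, track statistics
  sites.py        site quantification, quartiles, ratios, profiles
  contacts.py     balancing, expected, decay, insulation, loops, APA
  genes.py        CEN/TEL gene orientation, Mann-Whitney comparisons
  pipeline.py     end-to-end scenario runs and report comparison
  cli.py          `cenloop` command-line interface
docs/methods.md   model and algorithm notes, parameter defaults, limits
```
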