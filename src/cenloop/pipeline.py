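"""End-to-end scenario runs: simulate -> calibrate -> sites -> contacts ->
genes -> report.

Every stage consumes the previous stage's public data structures; the run
is deterministic given the seed (child seeds are spawned per stage from one
SeedSequence) and the report is a plain JSON-serializable dict in which
every number is traceable to an operation of the library.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .calibration import (
    call_peaks, nfe_track, normalization_factor, occupancy_ratio,
    peak_overlap_fraction, track_correlation,
)
from .contacts import (
    anchor_site_classification, balance_iterative, call_loops, classify_loops,
    decay_curve, distance_binned_cen_contact, expected_cis, insulation_score,
    average_score_profile, pileup,
)
from .core import ContactMap
from .genes import anchor_gene_comparison, flanking_genes, rpo21_activity
from .simulate import scenario, simulate_chip_counts, simulate_contact_map
from .sites import build_site_table, quantify_at_sites, ratio_analysis

__version__ = "0.1.0"

CHIP_PROTEINS = ("scc1", "scc2", "pds5", "rpo21")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Defaults follow the field-standard parameterization: peak threshold
    2.0 on 100-bp nFE bins, APA flank 10 kb with min distance 5 kb, loop
    calling with a 16-px window / 8-px peak at FDR 0.1 and 2.5-kb merge,
    insulation windows 5 and 10 kb, and a 5-kb pericentromeric exclusion.
    """

    scenario: str = "wt_like"
    seed: int = 0
    outdir: str | None = None
    peak_threshold: float = 2.0
    min_input_reads: float = 1.0
    site_window: int = 400
    cen_exclusion: int = 5000
    flank: int = 10_000
    min_dist: float = 5000.0
    fdr: float = 0.1
    merge_bp: float = 2500.0
    window_px: int = 16
    peak_px: int = 8
    insulation_windows: tuple[int, ...] = (5000, 10_000)
    cen_radius: int = 5000
    anchor_tolerance: int = 2500
    distance_edges: tuple[int, ...] = (0, 25_000, 50_000, 100_000, 200_000)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("insulation_windows", "distance_edges"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run one scenario end to end and return the report dict.

    When ``config.outdir`` is set, intermediate standard-format files
    (bedGraph tracks, peak BED, site TSV, loop BEDPE, decay TSV) and
    ``report.json`` are written there.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "scenario": config.scenario,
            "seed": config.seed,
            "version": __version__,
            "config": _jsonable(asdict(config)),
        }
    }

    try:
        sc = scenario(config.scenario)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("synthetic_data", exc) from exc
    ann = sc.annotation
    sizes = dict(ann.chromosomes)
    ss = np.random.SeedSequence(config.seed)
    chip_seeds, contact_seeds, rest = ss.spawn(3)
    chip_rngs = {
        (prot, role): np.random.default_rng(s)
        for (prot, role), s in zip(
            [(p, r) for p in CHIP_PROTEINS for r in ("sample", "control")],
            chip_seeds.spawn(2 * len(CHIP_PROTEINS)),
        )
    }

    # --- calibration stage -------------------------------------------------
    try:
        tracks = {}
        control_tracks = {}
        calib = {}
        for prot in CHIP_PROTEINS:
            res = simulate_chip_counts(sc.chip[prot], rng=chip_rngs[(prot, "sample")])
            if sc.name == "wt_like":
                ctrl = res
            else:
                ctrl = simulate_chip_counts(
                    sc.chip_control[prot], rng=chip_rngs[(prot, "control")]
                )
            or_s = occupancy_ratio(res.counts)
            or_c = occupancy_ratio(ctrl.counts)
            nf = normalization_factor(or_s, or_c)
            tracks[prot] = nfe_track(
                res.chip, res.input, nf, min_input_reads=config.min_input_reads
            )
            nf_c = normalization_factor(or_c, or_c)
            control_tracks[prot] = nfe_track(
                ctrl.chip, ctrl.input, nf_c, min_input_reads=config.min_input_reads
            )
            calib[prot] = {"or": or_s, "or_control": or_c, "nf": nf}
            if outdir:
                cio.write_track(tracks[prot], outdir / f"nfe_{prot}.bedgraph", sizes)
        report["calibration"] = calib
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("calibration", exc) from exc

    # --- peaks and correlations -------------------------------------------
    try:
        peaks = {
            prot: call_peaks(tracks[prot], threshold=config.peak_threshold)
            for prot in ("scc1", "scc2")
        }
        sites_list = ann.sites["cohesin"]
        report["peaks"] = {
            "n_scc1": len(peaks["scc1"]),
            "n_scc2": len(peaks["scc2"]),
            "scc2_overlap_scc1": peak_overlap_fraction(peaks["scc2"], peaks["scc1"]),
            "spearman_scc1_scc2_at_sites": track_correlation(
                tracks["scc1"], tracks["scc2"], at=sites_list,
                window=config.site_window,
            ),
        }
        if outdir:
            for prot, plist in peaks.items():
                cio.write_bed([p.interval for p in plist], outdir / f"peaks_{prot}.bed")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("peak_calling", exc) from exc

    # --- site analytics ----------------------------------------------------
    try:
        table = build_site_table(
            ann, tracks, collection="cohesin", window=config.site_window,
            exclusion=config.cen_exclusion, quartile_by="scc2",
        )
        arm = ~table["excluded"].to_numpy()
        ctrl_num = quantify_at_sites(control_tracks["scc2"], sites_list,
                                     window=config.site_window)
        ctrl_den = quantify_at_sites(control_tracks["scc1"], sites_list,
                                     window=config.site_window)
        ctrl_ratio = (ctrl_num / ctrl_den)[arm]
        rr = ratio_analysis(
            table["nfe_scc2"].to_numpy()[arm],
            table["nfe_scc1"].to_numpy()[arm],
            ctrl_ratio,
        )
        report["sites"] = {
            "n_sites": int(len(table)),
            "n_arm_sites": int(arm.sum()),
            "scc2_scc1_median_fold": rr.median_fold,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("site_analytics", exc) from exc

    # --- contact analytics -------------------------------------------------
    try:
        maps: dict[str, ContactMap] = {}
        expecteds = {}
        loops_all = []
        insul = {win: {} for win in config.insulation_windows}
        for chrom, cseed in zip(ann.chromosomes, contact_seeds.spawn(len(ann.chromosomes))):
            cmap = simulate_contact_map(
                sc.contacts[chrom], rng=np.random.default_rng(cseed)
            )
            cmap.weights = balance_iterative(cmap)
            cen = ann.centromeres[chrom]
            expecteds[chrom] = expected_cis(cmap, cen=cen)
            maps[chrom] = cmap
            loops_all.extend(
                call_loops(
                    cmap, cen=cen, expected=expecteds[chrom],
                    window_px=config.window_px, peak_px=config.peak_px,
                    fdr=config.fdr, merge_bp=config.merge_bp,
                    min_dist=config.min_dist,
                )
            )
            for win in config.insulation_windows:
                insul[win][chrom] = insulation_score(cmap, window=win)
            if outdir:
                cio.write_matrix(cmap, outdir / f"matrix_{chrom}.coo")
        summary = classify_loops(
            loops_all, ann, sites_list, cen_radius=config.cen_radius
        )
        flags, n_anchor, n_non = anchor_site_classification(
            sites_list, loops_all, ann, cen_radius=config.cen_radius,
            tolerance=config.anchor_tolerance,
        )
        table["anchor"] = flags
        flagged_names = {s.name for s, f in zip(sites_list, flags) if f}
        truth_names = set(sc.truth["anchor_sites"])
        anchor_agreement = (
            100.0 * len(flagged_names & truth_names) / len(flagged_names)
            if flagged_names else 100.0
        )
        cen_loops = [lp for lp in loops_all if lp.category == "centromere-originated"]
        apa = None
        usable = [
            (lp.anchor1, lp.anchor2) for lp in loops_all
            if lp.length > config.min_dist
        ]
        if usable:
            apa = pileup(
                maps, usable, expecteds=expecteds, flank=config.flank,
                min_dist=config.min_dist,
            )
        dec = decay_curve(list(maps.values()))
        win = max(config.insulation_windows)
        offs, mean_prof, _, _ = average_score_profile(
            insul[win], dict(ann.centromeres), flank=20_000
        )
        cen_min_offset = int(offs[int(np.nanargmin(mean_prof))])
        dist_tab = distance_binned_cen_contact(
            maps, [s for s, a in zip(sites_list, arm) if a], ann,
            list(config.distance_edges), expecteds=expecteds,
            flank=config.flank, min_dist=config.min_dist,
        )
        report["contacts"] = {
            "n_loops": len(loops_all),
            "categories": {
                row["category"]: {
                    "count": int(row["count"]),
                    "mean_length": row["mean_length"],
                    "median_length": row["median_length"],
                }
                for _, row in summary.iterrows()
            },
            "mean_cen_loop_length": (
                float(np.mean([lp.length for lp in cen_loops])) if cen_loops else None
            ),
            "apa_central_score": apa.central_score if apa else None,
            "anchor_sites": n_anchor,
            "non_anchor_sites": n_non,
            "anchor_truth_agreement_pct": anchor_agreement,
            "insulation_cen_min_offset": cen_min_offset,
            "n_boundaries": int(sum(
                len(t.boundaries) for t in insul[win].values()
            )),
            "decay_p_first": float(dec.p[0]),
            "distance_binned_central": _jsonable(
                dist_tab.to_dict(orient="records")
            ),
        }
        if outdir:
            cio.write_loops(loops_all, outdir / "loops.bedpe")
            np.savetxt(
                outdir / "decay.tsv",
                np.column_stack([dec.s, dec.p]),
                header="s_bp\tmean_contact", delimiter="\t", comments="",
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("contact_analytics", exc) from exc

    # --- gene context ------------------------------------------------------
    try:
        genes_by_chrom = ann.genes_by_chrom()
        arm_sites = [s for s, a in zip(sites_list, arm) if a]
        arm_flags = flags[arm]
        pairs, pair_flags = [], []
        for site, f in zip(arm_sites, arm_flags):
            fp = flanking_genes(site, genes_by_chrom[site.chrom], ann)
            if fp is not None:
                pairs.append(fp)
                pair_flags.append(f)
        rpo = rpo21_activity(ann.genes, tracks["rpo21"])
        rpo_by_name = {
            g.name: v for g, v in zip(ann.genes, rpo) if g.name is not None
        }
        gene_tests = anchor_gene_comparison(
            pairs, np.array(pair_flags), rpo21=rpo_by_name
        )
        report["genes"] = _jsonable(gene_tests)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("gene_context", exc) from exc

    # --- ground truth echo --------------------------------------------------
    report["truth"] = {
        "scc2_scc1_fold": sc.truth["scc2_scc1_fold"],
        "n_true_loops": int(len(sc.truth["loops"])),
        "mean_true_loop_length": sc.truth["mean_loop_length"],
        "mean_true_cen_loop_length": sc.truth["mean_cen_loop_length"],
        "anchor_sites": list(sc.truth["anchor_sites"]),
    }
    report = _jsonable(report)
    if outdir:
        table.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def compare_conditions(report_a: dict, report_b: dict) -> dict:
    """Side-by-side deltas and fold-changes of every shared numeric metric;
    metrics missing on one side are marked absent."""
    def walk(a, b, prefix=""):
        out = {}
        keys = set()
        for side in (a, b):
            if isinstance(side, dict):
                keys |= set(side)
        for k in sorted(keys):
            path = f"{prefix}.{k}" if prefix else str(k)
            va = a.get(k) if isinstance(a, dict) else None
            vb = b.get(k) if isinstance(b, dict) else None
            if isinstance(va, dict) or isinstance(vb, dict):
                out.update(walk(va or {}, vb or {}, path))
            elif isinstance(va, (int, float)) and isinstance(vb, (int, float)):
                entry = {"a": va, "b": vb, "delta": vb - va}
                entry["fold"] = vb / va if va else None
                out[path] = entry
            elif va is None or vb is None:
                out[path] = {"a": va, "b": vb, "absent": True}
        return out

    a_metrics = {k: v for k, v in report_a.items() if k != "provenance"}
    b_metrics = {k: v for k, v in report_b.items() if k != "provenance"}
    return walk(a_metrics, b_metrics)
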