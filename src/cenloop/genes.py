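"""Gene context of cohesin binding sites.

Yeast cohesin sites sit mostly in convergent intergenic regions.  Relative
to the centromere of their chromosome, the two flanking genes are labeled:

* CEN-oriented — the gene on the centromere-distal side of the site,
  transcribed toward the centromere;
* TEL-oriented — the gene on the centromere-proximal side, transcribed
  away from the centromere.

A long or strongly transcribed CEN-oriented gene is a candidate barrier to
centromere-initiated loop extrusion, so gene length and RNA-polymerase
(Rpo21) occupancy are compared between genes at anchor and non-anchor
cohesin sites with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BinnedTrack, GenomeAnnotation, GenomicInterval


@dataclass
class FlankingGenePair:
    """Nearest flanking genes of one cohesin site with orientation labels.

    ``cen_oriented`` / ``tel_oriented`` are None when the corresponding
    flank does not satisfy the orientation rule.
    """

    site: GenomicInterval
    left: GenomicInterval
    right: GenomicInterval
    convergent: bool
    cen_oriented: GenomicInterval | None
    tel_oriented: GenomicInterval | None


def flanking_genes(
    site: GenomicInterval,
    genes_sorted: list[GenomicInterval],
    annotation: GenomeAnnotation,
) -> FlankingGenePair | None:
    """Nearest non-containing gene on each side of a site, with CEN/TEL
    orientation labels; None when either flank is missing.

    Orientation is symmetric between arms: on the left arm the
    centromere-distal flank is the left gene and "toward the centromere"
    is the + strand; mirrored on the right arm.
    """
    if site.chrom not in annotation.centromeres:
        raise ValueError(f"no centromere for chromosome {site.chrom}")
    cen = annotation.centromeres[site.chrom]
    summit = site.midpoint
    starts = [g.start for g in genes_sorted]
    k = bisect_left(starts, summit)
    left = None
    for g in reversed(genes_sorted[:k]):
        if g.end <= summit:
            left = g
            break
    right = None
    for g in genes_sorted[k:]:
        if g.start > summit:
            right = g
            break
    if left is None or right is None:
        return None
    convergent = left.strand == "+" and right.strand == "-"
    on_left_arm = summit < cen
    distal, proximal = (left, right) if on_left_arm else (right, left)
    toward_cen = "+" if on_left_arm else "-"   # strand pointing at the CEN
    away_cen = "-" if on_left_arm else "+"
    cen_oriented = distal if distal.strand == toward_cen else None
    tel_oriented = proximal if proximal.strand == away_cen else None
    return FlankingGenePair(
        site=site, left=left, right=right, convergent=convergent,
        cen_oriented=cen_oriented, tel_oriented=tel_oriented,
    )


def compare_gene_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two gene groups.

    Exact enumeration of the U distribution when min(n, m) <= 8 and the
    pooled sample is tie-free; normal approximation with tie and
    continuity correction otherwise.  Returns (U of the first group,
    two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def rpo21_activity(
    genes: list[GenomicInterval],
    track: BinnedTrack,
) -> np.ndarray:
    """Per-gene transcription proxy: mean nFE over the gene body's unmasked
    bins (strand-agnostic); NaN for fully masked genes."""
    bs = track.bin_size
    out = np.full(len(genes), np.nan)
    for k, g in enumerate(genes):
        if g.chrom not in track.values:
            raise ValueError(f"gene on unknown chromosome {g.chrom}")
        v = track.values[g.chrom]
        m = track.mask[g.chrom]
        b0 = g.start // bs
        b1 = min((g.end - 1) // bs + 1, len(v))
        vals = v[b0:b1][~m[b0:b1]]
        if len(vals):
            out[k] = vals.mean()
    return out


def anchor_gene_comparison(
    pairs: list[FlankingGenePair],
    anchor_flags: np.ndarray,
    rpo21: dict[str, float] | None = None,
) -> dict:
    """Compare CEN- and TEL-oriented gene length (and optionally Rpo21 FE,
    keyed by gene name) between anchor and non-anchor cohesin sites.

    Returns per-orientation U statistics, two-sided p-values and group
    sizes."""
    out: dict = {}
    for label in ("cen_oriented", "tel_oriented"):
        ga = [getattr(p, label) for p, f in zip(pairs, anchor_flags)
              if f and getattr(p, label) is not None]
        gn = [getattr(p, label) for p, f in zip(pairs, anchor_flags)
              if not f and getattr(p, label) is not None]
        entry: dict = {"n_anchor": len(ga), "n_non_anchor": len(gn)}
        if ga and gn:
            u, p = compare_gene_groups(
                np.array([len(g) for g in ga]), np.array([len(g) for g in gn])
            )
            entry["length_U"], entry["length_p"] = u, p
            if rpo21 is not None:
                fa = [rpo21[g.name] for g in ga if g.name in rpo21]
                fn = [rpo21[g.name] for g in gn if g.name in rpo21]
                if fa and fn:
                    u, p = compare_gene_groups(np.array(fa), np.array(fn))
                    entry["rpo21_U"], entry["rpo21_p"] = u, p
        out[label] = entry
    return out
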