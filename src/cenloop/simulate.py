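"""Synthetic calibrated-ChIP and Micro-C-like data with known ground truth.

Two generators make every downstream stage testable without the deposited
sequencing data:

``simulate_chip_counts``
    Dual-genome ChIP read counts.  Target-species cells are mixed with
    spike-in cells at a fixed cell-equivalent ratio; input reads sample DNA
    content (near-uniform per bp), ChIP reads sample protein-bound chromatin
    (site enrichments on a flat background, times a global chromatin-bound
    fraction).  Reads are drawn multinomially, the simplest noise model
    consistent with count data.  With all enrichments equal to 1, the
    expected occupancy ratio equals the target's chromatin-bound fraction,
    so the ratio of bound fractions between two conditions is the ground
    truth that calibration must recover as NF.

``simulate_contact_map``
    Cis contact maps with expected intensity
    ``lambda(i,j) = C * |i-j|^-alpha`` times domain boosts, truncated
    2-D Gaussian loop dots, and a multiplicative attenuation for pairs
    spanning the centromere; counts are Poisson draws symmetrized over the
    upper triangle (``expectation=True`` returns lambda itself, useful as a
    noise-free control).

``scenario`` encodes the two study conditions ("wt_like": dense short
cohesin-cohesin loops, little Scc2 at arm sites; "wpl1_eco1_like": sparse
long centromere-anchored loops, Scc2/Scc1 ratio fold of 2.53 vs wild type)
on a four-chromosome toy genome, and exports the injected features as a
ground-truth manifest for recovery tests.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .calibration import ReadCounts
from .core import BinnedTrack, ContactMap, GenomeAnnotation, GenomicInterval

__all__ = [
    "ChipSimConfig", "ChipSimResult", "ContactSimConfig", "LoopSpec",
    "DomainSpec", "simulate_chip_counts", "simulate_contact_map",
    "scenario", "Scenario", "SCENARIO_NAMES",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# ChIP-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class ChipSimConfig:
    """Configuration of one two-species ChIP experiment (one condition).

    ``mixing_ratio`` is target:spike cell equivalents (2:1 in most
    experiments, 5:1 for low-abundance targets).  ``site_enrichments`` maps
    a site-collection name of the annotation to an enrichment factor
    (scalar, or an array with one factor per site); background is 1.
    ``bound_fraction`` scales the whole target ChIP signal per cell and is
    the quantity spike-in calibration recovers across conditions.
    ``input_noise`` is the coefficient of variation of multiplicative gamma
    noise on per-bin input samplability (0 = perfectly uniform).
    """

    annotation: GenomeAnnotation
    bin_size: int = 100
    spike_genome_size: int = 12_300_000
    mixing_ratio: float = 2.0
    depth: int = 4_000_000
    site_enrichments: dict[str, float | np.ndarray] = field(default_factory=dict)
    bound_fraction: float = 1.0
    input_noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.mixing_ratio <= 0:
            raise ValueError("mixing_ratio must be positive")
        if self.bound_fraction <= 0:
            raise ValueError("bound_fraction must be positive")
        for name, e in self.site_enrichments.items():
            if name not in self.annotation.sites:
                raise ValueError(f"unknown site collection {name!r}")
            arr = np.atleast_1d(np.asarray(e, dtype=float))
            if arr.min() < 1:
                raise ValueError(f"enrichment factors must be >= 1 ({name})")
            if arr.size not in (1, len(self.annotation.sites[name])):
                raise ValueError(f"enrichment array length mismatch for {name}")


@dataclass
class ChipSimResult:
    chip: BinnedTrack
    input: BinnedTrack
    counts: ReadCounts


def _bin_bp(length: int, bin_size: int) -> np.ndarray:
    n = math.ceil(length / bin_size)
    bp = np.full(n, float(bin_size))
    if length % bin_size:
        bp[-1] = length % bin_size
    return bp


def _target_weights(config: ChipSimConfig) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-chromosome (input, chip) sampling weights, in bp-equivalents."""
    ann = config.annotation
    bs = config.bin_size
    input_w = {c: _bin_bp(l, bs) for c, l in ann.chromosomes.items()}
    chip_w = {c: w.copy() for c, w in input_w.items()}
    for name, e in config.site_enrichments.items():
        sites = ann.sites[name]
        earr = np.broadcast_to(
            np.atleast_1d(np.asarray(e, dtype=float)), (len(sites),)
        )
        for site, ei in zip(sites, earr):
            b0 = site.start // bs
            b1 = (site.end - 1) // bs
            for b in range(b0, b1 + 1):
                lo = max(site.start, b * bs)
                hi = min(site.end, (b + 1) * bs)
                chip_w[site.chrom][b] += (ei - 1.0) * (hi - lo)
    return input_w, chip_w


def simulate_chip_counts(
    config: ChipSimConfig,
    rng: np.random.Generator | int | None = None,
    expectation: bool = False,
) -> ChipSimResult:
    """Draw one ChIP and one input fraction for a two-species mix.

    Returns raw binned target-genome tracks plus the four cross-species
    read totals needed for calibration.  ``expectation=True`` returns the
    exact expected counts instead of a multinomial draw.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    ann = config.annotation
    m = config.mixing_ratio
    input_w, chip_w = _target_weights(config)
    chroms = list(ann.chromosomes)
    lens = [len(input_w[c]) for c in chroms]
    offsets = np.concatenate([[0], np.cumsum(lens)])

    in_flat = np.concatenate([input_w[c] for c in chroms]) * m
    ch_flat = np.concatenate([chip_w[c] for c in chroms]) * m * config.bound_fraction
    in_full = np.concatenate([in_flat, [float(config.spike_genome_size)]])
    ch_full = np.concatenate([ch_flat, [float(config.spike_genome_size)]])
    if config.input_noise > 0 and not expectation:
        cv2 = config.input_noise ** 2
        in_full = in_full * rng.gamma(1.0 / cv2, cv2, size=in_full.shape)

    def draw(weights: np.ndarray) -> np.ndarray:
        p = weights / weights.sum()
        if expectation:
            return config.depth * p
        return rng.multinomial(config.depth, p).astype(float)

    in_counts = draw(in_full)
    ch_counts = draw(ch_full)

    def split(flat: np.ndarray) -> dict[str, np.ndarray]:
        return {
            c: flat[offsets[k]:offsets[k + 1]].copy()
            for k, c in enumerate(chroms)
        }

    chip_track = BinnedTrack(bin_size=config.bin_size, values=split(ch_counts),
                             semantics="raw")
    input_track = BinnedTrack(bin_size=config.bin_size, values=split(in_counts),
                              semantics="raw")
    counts = ReadCounts(
        chip_target=float(ch_counts[:-1].sum()),
        chip_spike=float(ch_counts[-1]),
        input_target=float(in_counts[:-1].sum()),
        input_spike=float(in_counts[-1]),
    )
    return ChipSimResult(chip=chip_track, input=input_track, counts=counts)


# ---------------------------------------------------------------------------
# Contact-map simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopSpec:
    """An injected loop dot: anchor positions (bp), enrichment E >= 1 and a
    Gaussian dot width (bp, one standard deviation; truncated at 3 sigma)."""

    anchor1: int
    anchor2: int
    enrichment: float
    width: float = 2000.0


@dataclass(frozen=True)
class DomainSpec:
    start: int
    end: int
    boost: float


@dataclass
class ContactSimConfig:
    chrom: str
    length: int
    bin_size: int = 1000
    depth: int = 3_000_000
    decay_exponent: float = 1.0
    loops: list[LoopSpec] = field(default_factory=list)
    domains: list[DomainSpec] = field(default_factory=list)
    centromere: int | None = None
    insulation_factor: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        if not 0 < self.insulation_factor <= 1:
            raise ValueError("insulation factor must be in (0, 1]")
        for lp in self.loops:
            if lp.enrichment < 1:
                raise ValueError("loop enrichment must be >= 1")
            if lp.anchor1 == lp.anchor2:
                raise ValueError("loop anchors must differ")
            for a in (lp.anchor1, lp.anchor2):
                if not 0 <= a < self.length:
                    raise ValueError("loop anchor outside chromosome")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.length / self.bin_size)


def expected_intensity(config: ContactSimConfig) -> np.ndarray:
    """Dense expected-count matrix lambda(i, j), scaled to the configured
    depth (full-matrix sum convention)."""
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    lam = np.maximum(d, 1).astype(float) ** (-config.decay_exponent)
    for dom in config.domains:
        b0, b1 = dom.start // config.bin_size, math.ceil(dom.end / config.bin_size)
        lam[b0:b1, b0:b1] *= dom.boost
    for lp in config.loops:
        c1 = min(lp.anchor1, lp.anchor2) // config.bin_size
        c2 = max(lp.anchor1, lp.anchor2) // config.bin_size
        sigma = max(lp.width / config.bin_size, 0.5)
        r = int(math.ceil(3 * sigma))
        di = np.arange(-r, r + 1)
        bump = (lp.enrichment - 1.0) * np.exp(
            -(di[:, None] ** 2 + di[None, :] ** 2) / (2 * sigma ** 2)
        )
        for ci, cj in ((c1, c2), (c2, c1)):
            r0, r1 = max(ci - r, 0), min(ci + r + 1, n)
            q0, q1 = max(cj - r, 0), min(cj + r + 1, n)
            sub = bump[r0 - (ci - r): r1 - (ci - r), q0 - (cj - r): q1 - (cj - r)]
            lam[r0:r1, q0:q1] *= 1.0 + sub
    if config.centromere is not None and config.insulation_factor < 1:
        cb = config.centromere // config.bin_size
        left = idx < cb
        right = idx > cb
        cross = np.logical_or(
            np.logical_and.outer(left, right), np.logical_and.outer(right, left)
        )
        lam[cross] *= config.insulation_factor
    lam *= config.depth / lam.sum()
    return lam


def simulate_contact_map(
    config: ContactSimConfig,
    rng: np.random.Generator | int | None = None,
    expectation: bool = False,
) -> ContactMap:
    """Poisson-sample a symmetric cis contact map from the expected
    intensity (or return the intensity itself with ``expectation=True``)."""
    lam = expected_intensity(config)
    if expectation:
        full = lam
    else:
        rng = _as_rng(config.seed if rng is None else rng)
        upper = np.triu(lam)
        cnt = rng.poisson(upper).astype(float)
        full = cnt + cnt.T - np.diag(np.diag(cnt))
    return ContactMap(
        chrom=config.chrom, bin_size=config.bin_size, counts=sp.csr_matrix(full)
    )


def loop_truth_table(config: ContactSimConfig) -> pd.DataFrame:
    """Ground-truth manifest of the injected loops of one map."""
    rows = [
        {
            "chrom": config.chrom,
            "anchor1": min(lp.anchor1, lp.anchor2),
            "anchor2": max(lp.anchor1, lp.anchor2),
            "length": abs(lp.anchor2 - lp.anchor1),
            "enrichment": lp.enrichment,
            "width": lp.width,
        }
        for lp in config.loops
    ]
    return pd.DataFrame(rows, columns=["chrom", "anchor1", "anchor2", "length",
                                       "enrichment", "width"])


# ---------------------------------------------------------------------------
# Study-condition scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("wt_like", "wpl1_eco1_like")

#: Target Scc2/Scc1 median nFE fold of the mutant-like condition vs wild
#: type, the headline affinity change the scenario injects.
SCC2_SCC1_TARGET_FOLD = 2.53

_LAYOUT_SEED = 20240317
_CHROMS = {"chrI": 350_000, "chrII": 500_000, "chrIII": 650_000, "chrIV": 800_000}
_CENS = {"chrI": 110_000, "chrII": 160_000, "chrIII": 300_000, "chrIV": 250_000}
#: centromere-to-anchor distances (bp) of the long mutant loops, alternating
#: left/right arm; their mean (~67 kb) is the condition's characteristic
#: loop length.
_MUT_LOOP_DISTS = (25_000, 40_000, 55_000, 75_000, 95_000, 130_000)
#: wild-type pericentromeric loop reach (bp), a few tens of kb.
_WT_CEN_DISTS = (12_000, 20_000)

_SITE_HALF = 120          # cohesin site half-width, bp
_GENE_GAP = 300           # intergenic gap between a site and its genes, bp
_CONTACT_DEPTH = 3_000_000
_CHIP_DEPTH = 4_000_000


@dataclass
class Scenario:
    """One study condition: annotation, per-protein ChIP configs (with the
    matched wild-type control configs for NF), per-chromosome contact
    configs, and the ground-truth manifest."""

    name: str
    annotation: GenomeAnnotation
    chip: dict[str, ChipSimConfig]
    chip_control: dict[str, ChipSimConfig]
    contacts: dict[str, ContactSimConfig]
    truth: dict


def _build_genome() -> dict:
    """Deterministic toy genome: chromosomes, centromeres, cohesin sites in
    convergent intergenic regions, flanking genes, per-gene transcription
    levels, and the mutant anchor-site selection."""
    rng = np.random.default_rng(_LAYOUT_SEED)
    site_pos: dict[str, list[int]] = {}
    for chrom, length in _CHROMS.items():
        cen = _CENS[chrom]
        pos: list[int] = []
        p = cen - 10_000
        while p > 15_000:
            pos.append(int(p))
            p -= rng.uniform(16_000, 24_000)
        p = cen + 10_000
        while p < length - 15_000:
            pos.append(int(p))
            p += rng.uniform(16_000, 24_000)
        site_pos[chrom] = sorted(pos)

    # mutant anchor sites: nearest site to each target distance, alternating arms
    anchors: dict[str, set[int]] = {c: set() for c in _CHROMS}
    for chrom in _CHROMS:
        cen = _CENS[chrom]
        for k, dist in enumerate(_MUT_LOOP_DISTS):
            side = -1 if k % 2 == 0 else 1
            target = cen + side * dist
            arm = [p for p in site_pos[chrom] if (p < cen) == (side < 0)]
            if not arm:
                continue
            best = min(arm, key=lambda p: abs(p - target))
            anchors[chrom].add(best)

    sites, genes, rpo21 = [], [], []
    gene_meta = []  # (site_index, role) parallel to genes
    for chrom in _CHROMS:
        cen = _CENS[chrom]
        for p in site_pos[chrom]:
            k = len(sites)
            is_anchor = p in anchors[chrom]
            sites.append(GenomicInterval(chrom, p - _SITE_HALF, p + _SITE_HALF,
                                         name=f"{chrom}_site{k}"))
            distal_left = p < cen  # distal-to-CEN side of the site
            for side in ("left", "right"):
                is_distal = (side == "left") == distal_left
                if is_distal and is_anchor:
                    length_bp = int(rng.uniform(3000, 4500))
                    act = rng.uniform(4.0, 7.0)
                else:
                    length_bp = int(rng.uniform(800, 2000))
                    act = rng.uniform(1.2, 3.0)
                if side == "left":
                    g = GenomicInterval(chrom, p - _GENE_GAP - length_bp,
                                        p - _GENE_GAP, strand="+",
                                        name=f"{chrom}_g{k}L")
                else:
                    g = GenomicInterval(chrom, p + _GENE_GAP,
                                        p + _GENE_GAP + length_bp, strand="-",
                                        name=f"{chrom}_g{k}R")
                genes.append(g)
                rpo21.append(act)
                gene_meta.append((k, "cen_oriented" if is_distal else "tel_oriented"))

    cen_flank = [
        GenomicInterval(c, _CENS[c] - 1500, _CENS[c] + 1500, name=f"{c}_CEN")
        for c in _CHROMS
    ]
    annotation = GenomeAnnotation(
        chromosomes=dict(_CHROMS),
        centromeres=dict(_CENS),
        genes=genes,
        sites={"cohesin": sites, "cen_flank": cen_flank, "gene_bodies": genes},
    )
    anchor_names = sorted(
        s.name for s in sites if s.midpoint in anchors[s.chrom]
    )
    return {
        "annotation": annotation,
        "site_pos": site_pos,
        "anchors": anchors,
        "anchor_names": anchor_names,
        "rpo21": np.array(rpo21),
        "gene_meta": gene_meta,
    }


@functools.lru_cache(maxsize=1)
def _genome() -> dict:
    return _build_genome()


def _chip_configs(e2_mut: float) -> tuple[dict[str, ChipSimConfig], dict[str, ChipSimConfig]]:
    """(wild-type, mutant-like) ChIP configs per protein."""
    ann = _genome()["annotation"]
    rpo21 = _genome()["rpo21"]

    def cfg(mix, enrich, bound):
        return ChipSimConfig(
            annotation=ann, mixing_ratio=mix, depth=_CHIP_DEPTH,
            site_enrichments=enrich, bound_fraction=bound,
        )

    wt = {
        "scc1": cfg(2.0, {"cohesin": 8.0, "cen_flank": 6.0}, 1.0),
        "scc2": cfg(5.0, {"cohesin": 1.3, "cen_flank": 10.0}, 1.0),
        "pds5": cfg(2.0, {"cohesin": 6.0, "cen_flank": 4.0}, 1.0),
        "rpo21": cfg(2.0, {"gene_bodies": rpo21}, 1.0),
    }
    mut = {
        "scc1": cfg(2.0, {"cohesin": 8.0, "cen_flank": 7.0}, 0.6),
        "scc2": cfg(5.0, {"cohesin": e2_mut, "cen_flank": 12.0}, 1.0),
        "pds5": cfg(2.0, {"cohesin": 2.0, "cen_flank": 8.0}, 0.9),
        "rpo21": cfg(2.0, {"gene_bodies": rpo21}, 1.0),
    }
    return wt, mut


def _expected_fold(e2_mut: float) -> float:
    """Expected Scc2/Scc1 median nFE fold (mutant vs WT) of the generator,
    computed from its noise-free expectation through the calibration math."""
    from .calibration import nfe_track, normalization_factor, occupancy_ratio
    from .sites import quantify_at_sites, ratio_analysis

    ann = _genome()["annotation"]
    sites = ann.sites["cohesin"]
    wt, mut = _chip_configs(e2_mut)
    vals = {}
    for cond, cfgs in (("wt", wt), ("mut", mut)):
        for prot in ("scc1", "scc2"):
            res = simulate_chip_counts(cfgs[prot], expectation=True)
            or_v = occupancy_ratio(res.counts)
            or_ctrl = occupancy_ratio(
                simulate_chip_counts(wt[prot], expectation=True).counts
            )
            nf = normalization_factor(or_v, or_ctrl)
            track = nfe_track(res.chip, res.input, nf, min_input_reads=0.0)
            vals[(cond, prot)] = quantify_at_sites(track, sites)
    ctrl = vals[("wt", "scc2")] / vals[("wt", "scc1")]
    res = ratio_analysis(vals[("mut", "scc2")], vals[("mut", "scc1")], ctrl)
    return res.median_fold


@functools.lru_cache(maxsize=1)
def _solved_scc2_enrichment() -> float:
    """Mutant arm-site Scc2 enrichment giving an expected Scc2/Scc1 fold of
    exactly SCC2_SCC1_TARGET_FOLD (root of the generator's own closed-form
    expectation; deterministic)."""
    return float(brentq(lambda e: _expected_fold(e) - SCC2_SCC1_TARGET_FOLD,
                        1.0 + 1e-9, 30.0, xtol=1e-6))


def _contact_configs(name: str) -> tuple[dict[str, ContactSimConfig], pd.DataFrame]:
    g = _genome()
    ann: GenomeAnnotation = g["annotation"]
    configs: dict[str, ContactSimConfig] = {}
    truth_frames = []
    for chrom, length in ann.chromosomes.items():
        cen = ann.centromeres[chrom]
        # (LoopSpec, is_cen_loop, distal anchor bp or None)
        entries: list[tuple[LoopSpec, bool, int | None]] = []
        if name == "wt_like":
            # short loops between adjacent cohesin sites within one arm
            pos = g["site_pos"][chrom]
            for a, b in zip(pos, pos[1:]):
                if (a < cen) == (b < cen):
                    entries.append((LoopSpec(a, b, enrichment=4.0, width=1500.0),
                                    False, None))
            for dist in _WT_CEN_DISTS:
                for side in (-1, 1):
                    arm = [p for p in pos if (p < cen) == (side < 0)]
                    if arm:
                        best = min(arm, key=lambda p: abs(p - (cen + side * dist)))
                        entries.append((LoopSpec(cen, best, enrichment=4.0,
                                                 width=1500.0), True, best))
        else:
            for p in sorted(g["anchors"][chrom]):
                entries.append((LoopSpec(cen, p, enrichment=6.0, width=2000.0),
                                True, p))
        # dedupe anchor pairs (two wt target distances may hit the same site)
        uniq: dict[tuple[int, int], tuple[LoopSpec, bool, int | None]] = {}
        for entry in entries:
            lp = entry[0]
            uniq[(min(lp.anchor1, lp.anchor2), max(lp.anchor1, lp.anchor2))] = entry
        entries = list(uniq.values())
        configs[chrom] = ContactSimConfig(
            chrom=chrom, length=length, bin_size=1000, depth=_CONTACT_DEPTH,
            decay_exponent=1.0, loops=[e[0] for e in entries], centromere=cen,
            insulation_factor=0.8 if name == "wt_like" else 0.3,
        )
        tab = loop_truth_table(configs[chrom])
        tab["cen_loop"] = [e[1] for e in entries]
        tab["distal_anchor"] = [e[2] if e[2] is not None else -1 for e in entries]
        truth_frames.append(tab)
    truth = pd.concat(truth_frames, ignore_index=True)
    return configs, truth


def scenario(name: str) -> Scenario:
    """Build the named study condition; deterministic given the name."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    g = _genome()
    wt_chip, mut_chip = _chip_configs(_solved_scc2_enrichment())
    chip = wt_chip if name == "wt_like" else mut_chip
    contacts, loop_truth = _contact_configs(name)
    cen_loops = loop_truth[loop_truth["cen_loop"]]
    distal = set(cen_loops["distal_anchor"])
    anchor_sites = sorted(
        s.name for s in g["annotation"].sites["cohesin"] if s.midpoint in distal
    )
    truth = {
        "scc2_scc1_fold": 1.0 if name == "wt_like" else SCC2_SCC1_TARGET_FOLD,
        "loops": loop_truth,
        "mean_loop_length": float(loop_truth["length"].mean()),
        "mean_cen_loop_length": float(cen_loops["length"].mean()),
        "anchor_sites": anchor_sites,
        "gene_meta": g["gene_meta"],
        "rpo21": g["rpo21"],
    }
    return Scenario(
        name=name,
        annotation=g["annotation"],
        chip=chip,
        chip_control=wt_chip,
        contacts=contacts,
        truth=truth,
    )
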