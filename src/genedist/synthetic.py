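"""Synthetic recombination maps, gene sets and evaluation scenarios.

The map simulator emulates the statistical structure of a genome-wide
bin map: a heavily zero-inflated, right-skewed per-bin rate distribution
(a large minority of bins with no recombination at all, a long upper tail
carrying most of the map length), optional hotspot bins, and uncovered
spans at telomeres and centromeres.  Rates are drawn from a zero-inflated
gamma whose default parameters were calibrated so that, on the
standardized (SRR) scale, the mixture reproduces the three hallmark mass
points of the human 10 Kb map as closely as a two-parameter gamma allows:
42.6% of bins at SRR = 0, about 79% below 1 and about 14% at SRR >= 2
(targets 78.4% and 12.9%; with the gamma mean pinned to 1 the two tail
constraints cannot both be met exactly).

The fixture registry provides hand-constructed micro-scenarios with
analytically known outputs, including an encoding of the 18-locus
region-overlap scorecard and the 43-candidate SNP-inclusion comparison
used to evaluate the two gene-unit definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compare import AssociationRegion, TopSNP
from .extend import ExtensionParams, GeneUnit
from .genes import GeneRecord
from .recmap import ChromBins, RecombinationMap

# zero-inflated gamma defaults: shape fit by least squares on the SRR-scale
# tail constraints with the scale forced so the mixture mean is exactly 1
DEFAULT_ZERO_FRACTION = 0.426
DEFAULT_GAMMA_SHAPE = 0.2951335
DEFAULT_GAMMA_SCALE = 5.9029567


@dataclass(frozen=True)
class GapSpec:
    """Uncovered spans per simulated chromosome, in bp.

    ``telomere`` bp are left uncovered at each chromosome end and a
    ``centromere`` gap of that length is centered mid-chromosome, mimicking
    where a pedigree-based map lacks informative meioses.
    """

    telomere: int = 1_000_000
    centromere: int = 3_000_000


@dataclass(frozen=True)
class MapSimParams:
    """Parameters of the zero-inflated-gamma map simulator.

    Defaults describe a scaled-down decode-like genome: 20 chromosomes of
    50 Mb on a 10 Kb grid.  ``hotspot_rate`` is the expected number of
    hotspot bins per Mb; hotspot bins have their positive rate multiplied
    by ``hotspot_intensity`` (the gamma tail already captures genome-wide
    skew, so hotspots default off).
    """

    n_chrom: int = 20
    chrom_length: int = 50_000_000
    bin_width: int = 10_000
    zero_fraction: float = DEFAULT_ZERO_FRACTION
    shape: float = DEFAULT_GAMMA_SHAPE
    scale: float = DEFAULT_GAMMA_SCALE
    hotspot_rate: float = 0.0
    hotspot_intensity: float = 10.0
    gaps: GapSpec = field(default_factory=GapSpec)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if 2 * self.gaps.telomere + self.gaps.centromere >= self.chrom_length:
            raise ValueError("gap spans exceed chromosome length")


@dataclass(frozen=True)
class GeneSimParams:
    """Parameters of the random gene-body generator.

    Lengths are lognormal (default median 25 kb, sigma 0.9 on the log
    scale, matching the broad spread of human protein-coding gene spans),
    clipped to at least 1 kb; bodies respect ``min_gap`` bp between
    neighbours and are placed only inside covered map spans.
    """

    n_genes: int = 500
    median_length: int = 25_000
    sigma_log: float = 0.9
    min_length: int = 1_000
    min_gap: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


def simulate_map(params: MapSimParams | None = None) -> RecombinationMap:
    """Draw a zero-inflated-gamma recombination map, reproducible from seed.

    Per covered bin the rate is 0 with probability ``zero_fraction`` and
    Gamma(shape, scale) otherwise; hotspot bins (Poisson-placed at
    ``hotspot_rate`` per Mb) have their positive rate multiplied by
    ``hotspot_intensity``.  The returned map is unstandardized.
    """
    params = params or MapSimParams()
    rng = np.random.default_rng(params.seed)
    bw = params.bin_width
    bins: dict[str, ChromBins] = {}
    for ci in range(1, params.n_chrom + 1):
        spans = _covered_spans(params.chrom_length, params.gaps, bw)
        starts_parts = [np.arange(s, e, bw, dtype=np.int64) for s, e in spans]
        starts = np.concatenate(starts_parts)
        ends = np.minimum(starts + bw, params.chrom_length)
        n = len(starts)
        rate = rng.gamma(params.shape, params.scale, size=n)
        rate[rng.random(n) < params.zero_fraction] = 0.0
        if params.hotspot_rate > 0:
            p_hot = params.hotspot_rate * bw / 1e6
            rate[rng.random(n) < p_hot] *= params.hotspot_intensity
        bins[f"chr{ci}"] = ChromBins(starts=starts, ends=ends, rate=rate)
    return RecombinationMap(bins=bins, bin_width=bw)


def _covered_spans(chrom_length: int, gaps: GapSpec, bin_width: int) -> list[tuple[int, int]]:
    """Covered [start, end) spans after cutting telomere/centromere gaps,
    snapped outward to the bin grid so coverage stays grid-aligned."""
    def snap_up(x):
        return ((x + bin_width - 1) // bin_width) * bin_width

    def snap_down(x):
        return (x // bin_width) * bin_width

    tel = gaps.telomere
    cen = gaps.centromere
    mid = chrom_length // 2
    spans = []
    if cen > 0:
        spans.append((snap_up(tel), snap_down(mid - cen // 2)))
        spans.append((snap_up(mid + cen // 2), snap_down(chrom_length - tel)))
    else:
        spans.append((snap_up(tel), snap_down(chrom_length - tel)))
    return [(s, e) for s, e in spans if e > s]


def simulate_genes(
    params: GeneSimParams | None = None, rmap: RecombinationMap | None = None
) -> list[GeneRecord]:
    """Place non-overlapping gene bodies inside the map's covered spans.

    Genes are allotted to spans proportionally to span length; within a
    span, placements are uniform subject to the ``min_gap`` spacing.  An
    allotment that cannot fit raises a packing error naming the span.
    """
    params = params or GeneSimParams()
    if rmap is None:
        rmap = simulate_map()
    rng = np.random.default_rng(params.seed)
    spans = [
        (chrom, s, e)
        for chrom, cb in rmap.bins.items()
        for s, e in _contiguous_spans(cb)
    ]
    if not spans and params.n_genes > 0:
        raise ValueError("map has no covered spans to place genes in")
    if params.n_genes == 0:
        return []
    weights = np.array([e - s for _, s, e in spans], dtype=float)
    alloc = rng.multinomial(params.n_genes, weights / weights.sum())
    mu = math.log(params.median_length)
    out: list[GeneRecord] = []
    gi = 1
    for (chrom, s, e), k in zip(spans, alloc):
        if k == 0:
            continue
        lengths = np.maximum(
            rng.lognormal(mu, params.sigma_log, size=k).astype(np.int64),
            params.min_length,
        )
        need = int(lengths.sum()) + (k - 1) * params.min_gap
        free = (e - s) - need
        if free < 0:
            raise ValueError(
                f"cannot pack {k} genes (need {need} bp) into span "
                f"{chrom}:[{s},{e}) of {e - s} bp; reduce n_genes or lengths"
            )
        offsets = np.sort(rng.uniform(0, free, size=k))
        cursor = np.concatenate([[0], np.cumsum(lengths[:-1] + params.min_gap)])
        starts = s + (offsets + cursor).astype(np.int64)
        for st, ln in zip(starts, lengths):
            out.append(
                GeneRecord(chrom=chrom, start=int(st), end=int(st + ln), name=f"SIM{gi:05d}")
            )
            gi += 1
    out.sort()
    return out


def _contiguous_spans(cb: ChromBins) -> list[tuple[int, int]]:
    spans = []
    start = int(cb.starts[0])
    for i in range(len(cb) - 1):
        if cb.starts[i + 1] != cb.ends[i]:
            spans.append((start, int(cb.ends[i])))
            start = int(cb.starts[i + 1])
    spans.append((start, int(cb.ends[-1])))
    return spans


def reference_extension(
    gene: GeneRecord, rmap: RecombinationMap, params: ExtensionParams | None = None
):
    """Naive reference for the cumulative-SRR walk, used as an oracle.

    Materializes the full outward bin list on each side of the gene,
    prefix-sums the SRR, and takes the first index at or past the
    threshold.  Returns (left, right, cum_left, cum_right, fb_left,
    fb_right) with the same fallback semantics as the walking
    implementation but none of its code.
    """
    params = params or ExtensionParams()
    cb = rmap.bins[gene.chrom]
    thr = params.srr_threshold

    def side(outward_idx, edge_of, contiguous, default_boundary):
        cum = 0.0
        last_edge = default_boundary
        prev = None
        for i in outward_idx:
            if prev is not None and not contiguous(prev, i):
                return last_edge, cum, True
            cum += float(cb.srr[i])
            last_edge = edge_of(i)
            if cum >= thr:
                return last_edge, cum, False
            prev = i
        return last_edge, cum, True

    # right side: every bin containing a base beyond the gene end, in order
    right_idx = [i for i in range(len(cb)) if cb.ends[i] > gene.end]
    if right_idx and cb.starts[right_idx[0]] > gene.end:
        r_res = (gene.end, 0.0, True)  # boundary falls in a gap
    else:
        r_res = side(
            right_idx,
            lambda i: int(cb.ends[i]),
            lambda p, i: cb.starts[i] == cb.ends[p],
            gene.end,
        )
    # left side: bins containing a base <= gene.start - 1, walked outward
    if gene.start == 0:
        l_res = (0, 0.0, False)
    else:
        left_idx = [i for i in range(len(cb)) if cb.starts[i] < gene.start][::-1]
        if left_idx and cb.ends[left_idx[0]] <= gene.start - 1:
            l_res = (gene.start, 0.0, True)
        else:
            l_res = side(
                left_idx,
                lambda i: int(cb.starts[i]),
                lambda p, i: cb.ends[i] == cb.starts[p],
                gene.start,
            )
    return l_res[0], r_res[0], l_res[1], r_res[1], l_res[2], r_res[2]


# ---------------------------------------------------------------------------
# fixture registry


@dataclass
class Fixture:
    """A bundled micro-scenario with its analytically expected outputs."""

    name: str
    rmap: RecombinationMap | None = None
    genes: list[GeneRecord] = field(default_factory=list)
    params: ExtensionParams = field(default_factory=ExtensionParams)
    regions: list[AssociationRegion] = field(default_factory=list)
    snps: list[TopSNP] = field(default_factory=list)
    defs: dict[str, list[GeneUnit]] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _uniform_map(n_bins: int = 100, rate: float = 1.0, chrom: str = "chr1") -> RecombinationMap:
    starts = np.arange(0, n_bins * 10_000, 10_000, dtype=np.int64)
    return RecombinationMap(
        bins={chrom: ChromBins(starts=starts, ends=starts + 10_000, rate=np.full(n_bins, rate))},
        bin_width=10_000,
    )


def _fixture_uniform() -> Fixture:
    rmap = _uniform_map()
    genes = [
        GeneRecord("chr1", 100_000, 200_000, "GENE1"),
        GeneRecord("chr1", 400_000, 450_000, "GENE2"),
        GeneRecord("chr1", 700_000, 780_000, "GENE3"),
    ]
    # all SRR = 1, threshold 2 -> exactly 2 bins = 20 kb per side
    return Fixture(
        name="uniform", rmap=rmap, genes=genes,
        expected={"ext_per_side": 20_000, "cum_srr": 2.0},
    )


def _fixture_staircase() -> Fixture:
    # rates chosen to sum to the bin count so the genome mean is ~1 and the
    # SRR sequence right of the gene is 0.5, 0.5, 0.9, 0.2 (hand-summed
    # cumulative 0.5, 1.0, 1.9, 2.1 -> stop at the 4th bin)
    rates = np.array([2.0, 2.0, 1.0, 0.9, 0.5, 0.5, 0.9, 0.2])
    starts = np.arange(0, 80_000, 10_000, dtype=np.int64)
    rmap = RecombinationMap(
        bins={"chr1": ChromBins(starts=starts, ends=starts + 10_000, rate=rates)},
        bin_width=10_000,
    )
    gene = GeneRecord("chr1", 30_000, 40_000, "STAIR1")
    return Fixture(
        name="staircase", rmap=rmap, genes=[gene],
        expected={
            "left": 10_000, "right": 80_000,
            "ext_left": 20_000, "ext_right": 40_000,
            "cum_srr_left": 3.0, "cum_srr_right": 2.1,
        },
    )


def _fixture_gap_fallback() -> Fixture:
    # coverage ends at 100 kb; the gene sits 2 low-SRR bins from the edge,
    # so the right walk runs out of map before reaching the threshold
    rates = np.full(10, 1.0)
    rates[8:] = 0.1
    starts = np.arange(0, 100_000, 10_000, dtype=np.int64)
    rmap = RecombinationMap(
        bins={"chr1": ChromBins(starts=starts, ends=starts + 10_000, rate=rates)},
        bin_width=10_000,
    )
    gene = GeneRecord("chr1", 70_000, 80_000, "NEAREND")
    return Fixture(
        name="gap-fallback", rmap=rmap, genes=[gene],
        expected={"fallback_right": True, "fallback_left": False},
    )


# printed per-locus rows of the 18-locus region-overlap evaluation:
# (cytoband, trait, expert gene count, extra under srr, extra under +/-50kb)
WTCCC_ROWS: tuple[tuple[str, str, int, int, int], ...] = (
    ("5p13", "CD", 0, 0, 0),
    ("10q24", "CD", 1, 0, 0),
    ("10q25", "T2D", 1, 0, 0),
    ("9p21", "CAD", 2, 0, 0),
    ("10q21", "CD", 3, 0, 0),
    ("16q12", "CD", 4, 0, 0),
    ("16q12", "T2D", 1, 0, 1),
    ("5q33", "CD", 2, 0, 1),
    ("1p13", "RA", 7, 0, 1),
    ("1p13", "T1D", 7, 0, 1),
    ("16p13", "T1D", 8, 0, 1),
    ("16p12", "BD", 9, 0, 1),
    ("1p31", "CD", 1, 0, 2),
    ("2q37", "CD", 1, 0, 2),
    ("18p11", "CD", 1, 0, 2),
    ("12q24", "T1D", 15, 0, 2),
    ("12q13", "T1D", 26, 0, 3),
    ("3p21", "CD", 18, 7, 9),
)


def _fixture_wtccc() -> Fixture:
    """Geometric encoding of the 18-locus scorecard rows.

    Each locus gets a 1 Mb region; expert genes lie inside it under both
    definitions, while 'extra' genes sit outside the region with a unit
    that reaches into it only under the definition that over-includes
    them.  Extras shared by both definitions (the dense low-recombination
    locus) overlap under both.
    """
    regions: list[AssociationRegion] = []
    srr_units: list[GeneUnit] = []
    fixed_units: list[GeneUnit] = []

    def add_unit(units, chrom, left, right, name, method, body=None):
        body = body or (left, right)
        g = GeneRecord(chrom, body[0], body[1], name)
        units.append(GeneUnit(gene=g, left=left, right=right, method=method))

    for j, (cyto, trait, n_expert, extra_srr, extra_fixed) in enumerate(WTCCC_ROWS):
        chrom = f"chr{cyto.split('p')[0].split('q')[0]}"
        base = 5_000_000 + j * 10_000_000
        start, end = base, base + 1_000_000
        label = f"{cyto}-{trait}"
        experts = tuple(f"{label}:G{k + 1}" for k in range(n_expert))
        regions.append(AssociationRegion(label, chrom, start, end, experts))
        for k, gname in enumerate(experts):
            gs = start + 100_000 + k * 30_000
            for units, method in ((srr_units, "srr"), (fixed_units, "fixed")):
                add_unit(units, chrom, gs, gs + 20_000, gname, method)
        n_both = min(extra_srr, extra_fixed)  # extras shared by both definitions
        for k in range(n_both):
            gname = f"{label}:X{k + 1}"
            gs, ge = end + 60_000 + k * 30_000, end + 70_000 + k * 30_000
            # both definitions reach back into the region
            add_unit(srr_units, chrom, end - 10_000, ge, gname, "srr", body=(gs, ge))
            add_unit(fixed_units, chrom, end - 5_000, ge, gname, "fixed", body=(gs, ge))
        for idx in range(extra_fixed - n_both):
            gname = f"{label}:F{idx + 1}"
            gs, ge = end + 20_000 + idx * 5_000, end + 30_000 + idx * 5_000
            # the 50 kb rule reaches back into the region; the srr unit stops short
            add_unit(fixed_units, chrom, gs - 50_000, ge + 50_000, gname, "fixed", body=(gs, ge))
            add_unit(srr_units, chrom, gs - 10_000, ge + 10_000, gname, "srr", body=(gs, ge))
    return Fixture(
        name="wtccc-loci",
        regions=regions,
        defs={"srr": srr_units, "fixed": fixed_units},
        expected={
            "total_expert": sum(r[2] for r in WTCCC_ROWS),
            "extra_srr": sum(r[3] for r in WTCCC_ROWS),
            "extra_fixed": sum(r[4] for r in WTCCC_ROWS),
            "concordant_loci": (17, 6),
            "n_loci": len(WTCCC_ROWS),
        },
    )


def _fixture_rbc() -> Fixture:
    """SNP-inclusion scenario for the 43 functional candidates.

    Of the 43 candidate genes, 3 are missed by both definitions, 1 more is
    missed only by the SRR rule and 7 more only by the +/-50 kb rule,
    matching the printed miss pattern of the red-blood-cell GWAS
    evaluation (total misses 4 vs 10).
    """
    snps: list[TopSNP] = []
    srr_units: list[GeneUnit] = []
    fixed_units: list[GeneUnit] = []
    statuses = ["both_miss"] * 3 + ["srr_miss"] * 1 + ["fixed_miss"] * 7 + ["hit"] * 32
    for k, status in enumerate(statuses):
        chrom = f"chr{(k % 20) + 1}"
        pos = 2_000_000 + k * 5_000_000
        gname = f"CAND{k + 1:02d}"
        snps.append(TopSNP(rsid=f"rs{1000 + k}", chrom=chrom, pos=pos, candidate_genes=(gname,)))
        srr_hits = status in ("hit", "fixed_miss")
        fixed_hits = status in ("hit", "srr_miss")
        # gene body right of the SNP: within 50 kb iff the fixed rule hits
        gs = pos + (40_000 if fixed_hits else 60_000)
        ge = gs + 20_000
        g = GeneRecord(chrom, gs, ge, gname)
        fixed_left = gs - 50_000  # contains pos iff gs - 50 kb <= pos
        srr_left = pos - 10_000 if srr_hits else pos + 20_000
        srr_units.append(GeneUnit(gene=g, left=srr_left, right=ge + 10_000, method="srr"))
        fixed_units.append(GeneUnit(gene=g, left=fixed_left, right=ge + 50_000, method="fixed"))
    return Fixture(
        name="rbc-candidates",
        snps=snps,
        defs={"srr": srr_units, "fixed": fixed_units},
        expected={
            "n_candidates": len(statuses),
            "missed_srr": 4,
            "missed_fixed": 10,
            "table_after_shared_excluded": (1, 39, 7, 33),
        },
    )


_REGISTRY = {
    "uniform": _fixture_uniform,
    "staircase": _fixture_staircase,
    "gap-fallback": _fixture_gap_fallback,
    "wtccc-loci": _fixture_wtccc,
    "rbc-candidates": _fixture_rbc,
}


def make_fixture(name: str) -> Fixture:
    """Build a registered micro-scenario by name.

    Raises a ValueError listing the registry for unknown names.
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return builder()
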