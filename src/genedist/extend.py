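"""Gene-unit construction: cumulative-SRR extensions and the fixed-distance rule.

The genetic-distance definition walks outward from each gene boundary over
the recombination-map grid, accumulating standardized recombination rate
(SRR) bin by bin, and stops at the first bin where the cumulative SRR
reaches a threshold (default 2).  The unit boundary is that bin's outer
edge, so an extension may be shorter than one bin width when the gene
boundary lies inside the first counted bin.  Bins lying entirely within
the gene body are never counted; the first counted bin is the one
containing the first base beyond the gene boundary, taken in full even
when it partially overlaps the gene.

Where map coverage runs out before the threshold is reached (telomeres,
centromeres, interior gaps) the side is flagged and its extension is
replaced by the median completed extension length of its chromosome,
pooling 5' and 3' sides; a chromosome with no completed extension falls
back to the genome-wide median.

The comparator definition simply adds a fixed physical distance (default
50 Kb) on each side, clipped at coordinate 0 and, when known, at the
chromosome length.

Strand is recorded but ignored: the walk is strand-symmetric, sides are
genomic left/right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneRecord
from .recmap import ChromBins, MapStateError, RecombinationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtensionParams:
    """Tunable parameters of both gene-unit definitions.

    srr_threshold : unitless cumulative SRR at which the walk stops (> 0).
    fixed_distance : bp added on each side by the physical-distance rule.
    bin_width : bp, the map's grid width.
    """

    srr_threshold: float = 2.0
    fixed_distance: int = 50_000
    bin_width: int = 10_000

    def __post_init__(self):
        if self.srr_threshold <= 0:
            raise ValueError("srr_threshold must be > 0")
        if self.fixed_distance < 0:
            raise ValueError("fixed_distance must be >= 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass
class GeneUnit:
    """A gene body plus left/right extensions under one definition.

    ``method`` is "srr" or "fixed".  For the srr method, ``cum_srr_*`` hold
    the attained cumulative SRR per side and ``fallback_*`` mark sides whose
    extension was (or must be) median-substituted.  Invariants:
    left <= gene.start, right >= gene.end, left >= 0.
    """

    gene: GeneRecord
    left: int
    right: int
    method: str
    cum_srr_left: float = 0.0
    cum_srr_right: float = 0.0
    fallback_left: bool = False
    fallback_right: bool = False

    def __post_init__(self):
        if not (0 <= self.left <= self.gene.start):
            raise ValueError(f"{self.gene.name}: left boundary {self.left} invalid")
        if self.right < self.gene.end:
            raise ValueError(f"{self.gene.name}: right boundary {self.right} invalid")

    @property
    def name(self) -> str:
        return self.gene.name

    @property
    def chrom(self) -> str:
        return self.gene.chrom

    @property
    def ext_left(self) -> int:
        return self.gene.start - self.left

    @property
    def ext_right(self) -> int:
        return self.right - self.gene.end

    def contains(self, pos: int) -> bool:
        return self.left <= pos < self.right

    def overlaps(self, start: int, end: int) -> bool:
        return max(self.left, start) < min(self.right, end)


def _walk_right(cb: ChromBins, boundary: int, threshold: float):
    """Accumulate SRR rightward from the bin containing position `boundary`.

    Returns (new_boundary, cum_srr, fallback).  `boundary` is the first base
    beyond the gene; if it falls in a coverage gap the walk fails at once.
    """
    i = int(np.searchsorted(cb.ends, boundary, side="right"))
    if i >= len(cb) or cb.starts[i] > boundary:
        return boundary, 0.0, True  # boundary in a gap / beyond coverage
    cum = 0.0
    while True:
        cum += float(cb.srr[i])
        if cum >= threshold:
            return int(cb.ends[i]), cum, False
        if i + 1 >= len(cb) or cb.starts[i + 1] != cb.ends[i]:
            return int(cb.ends[i]), cum, True  # provisional at last covered edge
        i += 1


def _walk_left(cb: ChromBins, boundary: int, threshold: float):
    """Mirror of :func:`_walk_right`: accumulate leftward from the bin
    containing position ``boundary - 1``."""
    if boundary <= 0:
        return 0, 0.0, False  # nothing beyond the chromosome origin
    pos = boundary - 1
    i = int(np.searchsorted(cb.starts, pos, side="right")) - 1
    if i < 0 or cb.ends[i] <= pos:
        return boundary, 0.0, True
    cum = 0.0
    while True:
        cum += float(cb.srr[i])
        if cum >= threshold:
            return int(cb.starts[i]), cum, False
        if i == 0 or cb.ends[i - 1] != cb.starts[i]:
            return int(cb.starts[i]), cum, True
        i -= 1


def extend_gene_srr(
    gene: GeneRecord, rmap: RecombinationMap, params: ExtensionParams | None = None
) -> GeneUnit:
    """Extend one gene under the cumulative-SRR rule, each side independently.

    Stops at the first bin where the cumulative SRR >= ``srr_threshold``
    (inclusive; the threshold may be overshot).  A gene boundary exactly on
    a bin edge starts counting at the next full bin outward.  Sides that
    run out of map coverage are returned with their fallback flag set and a
    provisional boundary at the last covered edge; :func:`apply_fallback`
    replaces those extensions.

    Raises
    ------
    MapStateError if the map is not standardized; KeyError if the gene's
    chromosome is absent from the map.
    """
    params = params or ExtensionParams()
    if not rmap.standardized:
        raise MapStateError("map is not standardized; call standardize() first")
    if gene.chrom not in rmap.bins:
        raise KeyError(f"gene {gene.name}: chromosome {gene.chrom} absent from map")
    cb = rmap.bins[gene.chrom]
    left, cum_l, fb_l = _walk_left(cb, gene.start, params.srr_threshold)
    right, cum_r, fb_r = _walk_right(cb, gene.end, params.srr_threshold)
    return GeneUnit(
        gene=gene, left=left, right=right, method="srr",
        cum_srr_left=cum_l, cum_srr_right=cum_r,
        fallback_left=fb_l, fallback_right=fb_r,
    )


def apply_fallback(units: list[GeneUnit], params: ExtensionParams | None = None) -> list[GeneUnit]:
    """Replace flagged extensions by the per-chromosome median completed length.

    The median pools completed (non-fallback) 5' and 3' extension lengths of
    each chromosome; it is computed after all walks on the chromosome finish.
    A chromosome with no completed extension uses the genome-wide median
    (logged).  Replaced left boundaries are clipped at coordinate 0.  Units
    are modified copies; input order is preserved.
    """
    del params  # lengths are medians of realized extensions; no parameter enters
    completed: dict[str, list[int]] = {}
    for u in units:
        if u.method != "srr":
            raise ValueError("apply_fallback expects srr-method units")
        if not u.fallback_left:
            completed.setdefault(u.chrom, []).append(u.ext_left)
        if not u.fallback_right:
            completed.setdefault(u.chrom, []).append(u.ext_right)

    pooled = [x for v in completed.values() for x in v]
    genome_median = int(round(float(np.median(pooled)))) if pooled else 0

    def chrom_median(chrom: str) -> int:
        lens = completed.get(chrom)
        if not lens:
            logger.warning(
                "chromosome %s has no completed extensions; using genome-wide median %d bp",
                chrom, genome_median,
            )
            return genome_median
        return int(round(float(np.median(lens))))

    out: list[GeneUnit] = []
    for u in units:
        if not (u.fallback_left or u.fallback_right):
            out.append(u)
            continue
        med = chrom_median(u.chrom)
        left = max(0, u.gene.start - med) if u.fallback_left else u.left
        right = u.gene.end + med if u.fallback_right else u.right
        out.append(
            GeneUnit(
                gene=u.gene, left=left, right=right, method="srr",
                cum_srr_left=u.cum_srr_left, cum_srr_right=u.cum_srr_right,
                fallback_left=u.fallback_left, fallback_right=u.fallback_right,
            )
        )
    return out


def extend_gene_fixed(
    gene: GeneRecord,
    params: ExtensionParams | None = None,
    chrom_length: int | None = None,
) -> GeneUnit:
    """Extend one gene by ``fixed_distance`` bp on each side.

    The left boundary is clipped at 0; the right at ``chrom_length`` when
    provided (map coverage is not a clip: it ends before the physical
    chromosome end).
    """
    params = params or ExtensionParams()
    left = max(0, gene.start - params.fixed_distance)
    right = gene.end + params.fixed_distance
    if chrom_length is not None:
        right = min(right, max(chrom_length, gene.end))
    return GeneUnit(gene=gene, left=left, right=right, method="fixed")


def build_gene_units(
    genes: list[GeneRecord],
    rmap: RecombinationMap | None,
    params: ExtensionParams | None = None,
    method: str = "srr",
    chrom_lengths: dict[str, int] | None = None,
    on_error: str = "raise",
) -> list[GeneUnit]:
    """Build one unit per gene under the chosen definition.

    ``method="srr"`` runs the cumulative-SRR walk then median fallback per
    chromosome; ``method="fixed"`` applies the physical-distance rule (the
    map may be None).  Output ordering is deterministic: chromosome, then
    left boundary, then name.  ``on_error="skip"`` logs and drops genes that
    fail (e.g. chromosome absent from map) instead of raising.
    """
    params = params or ExtensionParams()
    if method not in ("srr", "fixed"):
        raise ValueError(f"unknown method {method!r}")
    units: list[GeneUnit] = []
    for gene in genes:
        try:
            if method == "srr":
                if rmap is None:
                    raise ValueError("srr method requires a recombination map")
                units.append(extend_gene_srr(gene, rmap, params))
            else:
                cl = (chrom_lengths or {}).get(gene.chrom)
                units.append(extend_gene_fixed(gene, params, chrom_length=cl))
        except (KeyError, ValueError, MapStateError) as exc:
            if on_error == "skip":
                logger.warning("skipping gene %s: %s", gene.name, exc)
            else:
                raise
    if method == "srr":
        n_fb = sum(u.fallback_left or u.fallback_right for u in units)
        if n_fb:
            logger.info("%d of %d genes need median fallback", n_fb, len(units))
        units = apply_fallback(units, params)
    units.sort(key=lambda u: (_chrom_sort_key(u.chrom), u.left, u.name))
    return units


def _chrom_sort_key(chrom: str):
    name = chrom.removeprefix("chr")
    return (0, int(name), "") if name.isdigit() else (1, 0, name)


def write_units(units: list[GeneUnit], path, bed: bool = False, one_based: bool = False) -> None:
    """Write the tabulated definition file: chromosome, left, right, name.

    The default layout is the 4-column plain-text definition table with a
    header comment stating the coordinate convention; ``bed=True`` emits
    BED4 instead (always 0-based half-open, no header).  Output is
    deterministic: identical inputs give byte-identical files.
    """
    with open(path, "w") as fh:
        if not bed:
            base = "1-based inclusive" if one_based else "0-based half-open"
            fh.write(f"# coordinates: {base}; columns: chrom, left, right, name\n")
        for u in units:
            left = u.left + 1 if (one_based and not bed) else u.left
            fh.write(f"{u.chrom}\t{left}\t{u.right}\t{u.name}\n")


def read_units(path, method: str = "srr") -> list[GeneUnit]:
    """Read a 4-column definition file back into units.

    Extension bookkeeping (cumulative SRR, fallback flags) is not stored in
    the file; the gene body is taken to be the full unit, which is enough
    for the overlap/containment evaluation operations.
    """
    units = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, left, right, name = line.rstrip("\n").split("\t")[:4]
            g = GeneRecord(chrom=chrom, start=int(left), end=int(right), name=name)
            units.append(GeneUnit(gene=g, left=int(left), right=int(right), method=method))
    return units
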