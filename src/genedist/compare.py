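"""Evaluation machinery for gene-unit definitions.

Covers four kinds of comparison:

* distribution summaries of extension lengths (median, IQR, tail fractions);
* boundary concordance between two definitions at a bp tolerance, per
  extension and per gene (both sides simultaneously);
* gene lists per labeled association region (any-overlap rule) and per top
  SNP (containment rule), scored against expert gene lists as extra/missing
  counts;
* exact one-tailed Fisher tests on 2x2 tables, computed with rational
  arithmetic so the hypergeometric tail is exact to double precision.

All intervals are 0-based half-open, so a unit touching a region boundary
does not overlap it and a SNP at a unit's right edge is outside.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .extend import GeneUnit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRegion:
    """A labeled association interval with an optional expert gene list."""

    locus: str
    chrom: str
    start: int
    end: int
    expert_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.locus}: start >= end")


@dataclass(frozen=True)
class TopSNP:
    """A top associated SNP with optional functional candidate gene names."""

    rsid: str
    chrom: str
    pos: int
    candidate_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"SNP {self.rsid}: negative position")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are definitions, columns outcome/complement."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ExtensionLengthSummary:
    """Median/IQR (Kb) and tail fractions of pooled per-side extension lengths."""

    median: float
    iqr_low: float
    iqr_high: float
    fraction_below: dict[float, float]
    fraction_above: dict[float, float]
    n_extensions: int


@dataclass(frozen=True)
class ConcordanceSummary:
    """Boundary agreement between two definitions at a bp tolerance."""

    tolerance: int
    fraction_per_extension: float
    fraction_per_gene: float
    n_genes: int


def extension_length_summary(
    units: list[GeneUnit], cutoffs: tuple[float, ...] = (10.0, 500.0)
) -> ExtensionLengthSummary:
    """Summarize pooled 5'/3' extension lengths (two per gene), in Kb.

    Quartiles use linear interpolation of order statistics (numpy default).
    ``cutoffs`` are Kb thresholds for which strictly-below and strictly-above
    tail fractions are reported.
    """
    if not units:
        raise ValueError("no units to summarize")
    methods = {u.method for u in units}
    if len(methods) > 1:
        raise ValueError(f"units mix methods {sorted(methods)}")
    kb = np.array([e for u in units for e in (u.ext_left, u.ext_right)], dtype=float) / 1e3
    q1, med, q3 = np.percentile(kb, [25, 50, 75])
    return ExtensionLengthSummary(
        median=float(med),
        iqr_low=float(q1),
        iqr_high=float(q3),
        fraction_below={c: float(np.mean(kb < c)) for c in cutoffs},
        fraction_above={c: float(np.mean(kb > c)) for c in cutoffs},
        n_extensions=len(kb),
    )


def boundary_concordance(
    units_a: list[GeneUnit], units_b: list[GeneUnit], tolerance: int = 10_000
) -> ConcordanceSummary:
    """Fraction of boundaries within ``tolerance`` bp between two definitions.

    Units are matched by gene name; names present in only one set are
    excluded and logged.  Per-extension counts left/left and right/right
    pairs separately; per-gene requires both sides of a gene to agree.
    """
    a = {u.name: u for u in units_a}
    b = {u.name: u for u in units_b}
    shared = sorted(a.keys() & b.keys())
    dropped = (a.keys() | b.keys()) - set(shared)
    if dropped:
        logger.warning("%d genes present in only one definition set; excluded", len(dropped))
    if not shared:
        raise ValueError("no genes shared between the two unit sets")
    left_ok = np.array([abs(a[g].left - b[g].left) <= tolerance for g in shared])
    right_ok = np.array([abs(a[g].right - b[g].right) <= tolerance for g in shared])
    return ConcordanceSummary(
        tolerance=int(tolerance),
        fraction_per_extension=float((left_ok.sum() + right_ok.sum()) / (2 * len(shared))),
        fraction_per_gene=float(np.mean(left_ok & right_ok)),
        n_genes=len(shared),
    )


def genes_overlapping_region(units: list[GeneUnit], region: AssociationRegion) -> list[str]:
    """Names of units with any overlap with the region (half-open), sorted.

    Any part of the unit falling inside the region suffices; a unit that
    merely touches a boundary does not overlap.
    """
    return sorted(
        u.name for u in units
        if u.chrom == region.chrom and u.overlaps(region.start, region.end)
    )


def genes_containing_position(units: list[GeneUnit], snp: TopSNP) -> list[str]:
    """Names of units whose [left, right) contains the SNP position, sorted."""
    return sorted(u.name for u in units if u.chrom == snp.chrom and u.contains(snp.pos))


def locus_scorecard(
    defs: dict[str, list[GeneUnit]], regions: list[AssociationRegion]
) -> pd.DataFrame:
    """Score each definition's region gene lists against the expert lists.

    For every locus and method: ``extra`` = genes returned by the overlap
    rule but absent from the expert list; ``missing`` = expert genes not
    returned.  The result has one row per locus plus a ``Total`` row, with
    columns ``locus``, ``expert`` and ``{method}_extra`` /
    ``{method}_missing`` per method.
    """
    rows = []
    for region in regions:
        row: dict = {"locus": region.locus, "expert": len(region.expert_genes)}
        expert = set(region.expert_genes)
        for method, units in defs.items():
            found = set(genes_overlapping_region(units, region))
            row[f"{method}_extra"] = len(found - expert)
            row[f"{method}_missing"] = len(expert - found)
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"locus": "Total", **{c: int(df[c].sum()) for c in df.columns if c != "locus"}}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def concordant_loci_table(
    scorecard: pd.DataFrame, method_a: str = "srr", method_b: str = "fixed"
) -> ContingencyTable2x2:
    """2x2 of fully concordant loci (no extra, no missing genes) per method.

    Row 1 counts method_a's concordant/discordant loci, row 2 method_b's;
    a one-tailed test with direction ``row1_higher`` asks whether method_a
    is concordant at more loci.
    """
    per_locus = scorecard[scorecard["locus"] != "Total"]
    n = len(per_locus)
    conc_a = int(((per_locus[f"{method_a}_extra"] == 0) & (per_locus[f"{method_a}_missing"] == 0)).sum())
    conc_b = int(((per_locus[f"{method_b}_extra"] == 0) & (per_locus[f"{method_b}_missing"] == 0)).sum())
    return ContingencyTable2x2(conc_a, n - conc_a, conc_b, n - conc_b)


def candidate_inclusion(
    defs: dict[str, list[GeneUnit]], snps: list[TopSNP]
) -> pd.DataFrame:
    """Per-SNP candidate hits and misses under each definition.

    A candidate gene is hit when its unit under the definition contains the
    top SNP position.  Returns one row per (snp, candidate) with boolean
    ``{method}_hit`` columns.
    """
    rows = []
    for snp in snps:
        for cand in snp.candidate_genes:
            row: dict = {"rsid": snp.rsid, "candidate": cand}
            for method, units in defs.items():
                hits = genes_containing_position(units, snp)
                row[f"{method}_hit"] = cand in hits
            rows.append(row)
    return pd.DataFrame(rows)


def candidate_miss_table(
    inclusion: pd.DataFrame,
    method_a: str = "srr",
    method_b: str = "fixed",
    exclude_shared: bool = True,
) -> ContingencyTable2x2:
    """2x2 of missed vs hit candidates per definition.

    With ``exclude_shared`` (default), candidates missed by both definitions
    are removed from both margins before testing, so the comparison isolates
    the misses each definition adds on its own.  Row 1 is method_a
    (missed, hit), row 2 method_b; direction ``row1_lower`` asks whether
    method_a misses fewer candidates.
    """
    miss_a = ~inclusion[f"{method_a}_hit"]
    miss_b = ~inclusion[f"{method_b}_hit"]
    keep = ~(miss_a & miss_b) if exclude_shared else np.ones(len(inclusion), dtype=bool)
    n = int(keep.sum())
    a = int((miss_a & keep).sum())
    c = int((miss_b & keep).sum())
    return ContingencyTable2x2(a, n - a, c, n - c)


def fisher_exact_one_tailed(table: ContingencyTable2x2, direction: str) -> float:
    """Exact one-tailed Fisher test on a 2x2 table with fixed margins.

    Under the null, the top-left cell X follows the hypergeometric
    distribution with the table's margins.  ``row1_lower`` returns
    P(X <= a); ``row1_higher`` returns P(X >= a).  The tail is summed in
    exact rational arithmetic and converted to float at the end, so the
    relative error is below 1e-15.  Degenerate margins (an empty row or
    column) give p = 1.0 with a warning: the table carries no information.
    """
    if direction not in ("row1_lower", "row1_higher"):
        raise ValueError(f"direction must be row1_lower or row1_higher, got {direction!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.n
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margins: p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = range(lo, a + 1) if direction == "row1_lower" else range(a, hi + 1)
    num = sum(math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in ks)
    return float(Fraction(num, math.comb(n, r1)))


# ---------------------------------------------------------------------------
# file readers for the evaluation inputs


def read_regions(path, expert_path=None) -> list[AssociationRegion]:
    """Read association regions as BED4 (chrom, start, end, locus label).

    ``expert_path`` optionally maps locus -> comma-separated expert gene
    names, tab-delimited.
    """
    expert: dict[str, tuple[str, ...]] = {}
    if expert_path is not None:
        with open(expert_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                locus = parts[0]
                names = tuple(g for g in parts[1].split(",") if g) if len(parts) > 1 else ()
                expert[locus] = names
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, locus = line.rstrip("\n").split("\t")[:4]
            regions.append(
                AssociationRegion(
                    locus=locus, chrom=chrom, start=int(start), end=int(end),
                    expert_genes=expert.get(locus, ()),
                )
            )
    return regions


def read_snps(path) -> list[TopSNP]:
    """Read top SNPs as tab-delimited chrom, pos, rsid[, candidates].

    The optional fourth column is a comma-separated candidate gene list.
    """
    snps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            cands = tuple(g for g in parts[3].split(",") if g) if len(parts) > 3 else ()
            snps.append(
                TopSNP(rsid=parts[2], chrom=parts[0], pos=int(parts[1]), candidate_genes=cands)
            )
    return snps
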