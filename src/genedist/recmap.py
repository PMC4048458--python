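"""Fixed-width-bin recombination maps and their standardization.

A recombination map is a genome-wide grid of fixed-width bins (10 Kb by
default), each carrying a sex-averaged recombination rate in cM/Mb.  The
standardized recombination rate (SRR) of a bin is its rate divided by the
genome-wide mean rate, so SRR = 1 marks average recombination and the mean
SRR over covered bins is exactly 1.  Because recombination is concentrated
in hotspots, the SRR distribution is heavily zero-inflated and right-skewed:
in the human genome roughly 40% of 10 Kb bins show no recombination at all
while a small minority carry most of the genetic map length.

Coordinates are 0-based half-open throughout; readers convert 1-based
dialects at the boundary.  Gaps (missing bins) are permitted and detectable;
they arise at telomeres and centromeres where the map has no coverage.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

#: Mean-SRR conservation tolerance.
MEAN_TOL = 1e-9


class MapFormatError(ValueError):
    """Raised when a map file fails parsing or grid validation."""


class MapStateError(RuntimeError):
    """Raised when an operation requires a (un)standardized map."""


@dataclass(frozen=True)
class MapDialect:
    """Column layout of a tab-delimited bin-map file.

    ``columns`` gives the positional meaning of the file's columns; it must
    contain "chrom", "start", "end" and "rate" (extra names are ignored
    columns).  ``one_based`` marks files whose start coordinate is 1-based
    inclusive, converted to 0-based half-open on read.  ``allow_short_terminal``
    accepts a final short bin per chromosome (chromosome length not a
    multiple of the bin width); short bins count with full weight.
    """

    columns: tuple[str, ...] = ("chrom", "start", "end", "rate")
    one_based: bool = False
    allow_short_terminal: bool = True
    comment: str = "#"


#: Named dialect presets. "decode-10kb" is the deCODE-style 10 Kb grid.
DIALECTS: dict[str, MapDialect] = {
    "default": MapDialect(),
    "decode-10kb": MapDialect(allow_short_terminal=True),
}


@dataclass
class ChromBins:
    """Sorted, grid-aligned bins of one chromosome as parallel arrays."""

    starts: np.ndarray  # int64, sorted ascending
    ends: np.ndarray    # int64
    rate: np.ndarray    # float64, cM/Mb
    srr: np.ndarray | None = None  # float64, set by standardize()

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    def gap_after(self) -> np.ndarray:
        """Boolean mask: True where a coverage gap follows bin i."""
        out = np.zeros(len(self.starts), dtype=bool)
        if len(self.starts) > 1:
            out[:-1] = self.starts[1:] != self.ends[:-1]
        return out


@dataclass
class RecombinationMap:
    """Per-chromosome ordered bins plus derived standardization state.

    Invariants: within a chromosome bins are sorted, non-overlapping and
    grid-aligned (starts are multiples of ``bin_width``); after
    :meth:`standardize`, the mean of ``srr`` over all covered bins equals 1
    within ``MEAN_TOL``.
    """

    bins: dict[str, ChromBins]
    bin_width: int = 10_000
    genome_mean_rate: float | None = None  # set by standardize()

    @property
    def standardized(self) -> bool:
        return self.genome_mean_rate is not None

    @property
    def chroms(self) -> list[str]:
        return list(self.bins)

    @property
    def n_bins(self) -> int:
        return sum(len(cb) for cb in self.bins.values())

    @property
    def chrom_spans(self) -> dict[str, tuple[int, int]]:
        return {c: cb.span for c, cb in self.bins.items()}

    def all_rates(self) -> np.ndarray:
        return np.concatenate([cb.rate for cb in self.bins.values()])

    def all_srr(self) -> np.ndarray:
        if not self.standardized:
            raise MapStateError("map is not standardized; call standardize() first")
        return np.concatenate([cb.srr for cb in self.bins.values()])

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: chrom, start, end, rate[, srr]."""
        parts = []
        for chrom, cb in self.bins.items():
            d = {"chrom": chrom, "start": cb.starts, "end": cb.ends, "rate": cb.rate}
            if cb.srr is not None:
                d["srr"] = cb.srr
            parts.append(pd.DataFrame(d))
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class SrrDistributionSummary:
    """Histogram of SRR values over half-open intervals, plus key fractions."""

    interval_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]
    fractions: tuple[float, ...]
    fraction_zero: float
    fraction_below_one: float
    fraction_at_least_threshold: float
    threshold: float
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        e = self.interval_edges
        return pd.DataFrame(
            {
                "interval_start": e[:-1],
                "interval_end": e[1:],
                "count": self.bin_counts,
                "fraction": self.fractions,
            }
        )


def _open_text(path) -> io.TextIOBase:
    # transparent gzip by magic bytes, not extension
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def read_recombination_map(
    path,
    dialect: MapDialect | str = "default",
    bin_width: int | None = None,
    autosomes_only: bool = True,
) -> RecombinationMap:
    """Read and grid-validate a tab-delimited bin map.

    Parameters
    ----------
    path : path-like
        Tab-delimited text, optionally gzipped: one row per bin with the
        columns named by the dialect (default chrom, start, end, rate).
    dialect : MapDialect or preset name
        Column layout and coordinate-base handling; see :data:`DIALECTS`.
    bin_width : int, optional
        Expected grid width in bp.  Inferred from the modal bin width when
        omitted, then enforced.
    autosomes_only : bool
        Skip non-autosomal records with a logged warning (default), matching
        the autosomal scope of the gene catalogue.

    Raises
    ------
    MapFormatError
        On malformed rows (naming the line), negative rates, duplicate,
        overlapping or grid-misaligned bins, or an empty file.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise MapFormatError(
                f"unknown map dialect {dialect!r}; presets: {sorted(DIALECTS)}"
            ) from None

    idx = {name: i for i, name in enumerate(dialect.columns)}
    for req in ("chrom", "start", "end", "rate"):
        if req not in idx:
            raise MapFormatError(f"dialect lacks required column {req!r}")

    rows: dict[str, list[tuple[int, int, float]]] = {}
    n_skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(dialect.comment):
                continue
            parts = line.split("\t")
            if len(parts) < len(dialect.columns):
                raise MapFormatError(
                    f"{path}:{lineno}: expected {len(dialect.columns)} columns, got {len(parts)}"
                )
            try:
                chrom = parts[idx["chrom"]]
                start = int(parts[idx["start"]])
                end = int(parts[idx["end"]])
                rate = float(parts[idx["rate"]])
            except ValueError as exc:
                raise MapFormatError(f"{path}:{lineno}: {exc}") from None
            if dialect.one_based:
                start -= 1
            if rate < 0:
                raise MapFormatError(f"{path}:{lineno}: negative rate {rate}")
            if end <= start:
                raise MapFormatError(f"{path}:{lineno}: empty bin [{start},{end})")
            if autosomes_only and chrom not in AUTOSOMES:
                n_skipped += 1
                continue
            rows.setdefault(chrom, []).append((start, end, rate))

    if n_skipped:
        logger.warning("skipped %d non-autosomal map rows", n_skipped)
    if not rows:
        raise MapFormatError(f"{path}: no usable map rows")

    widths = np.concatenate(
        [np.array([e - s for s, e, _ in rr], dtype=np.int64) for rr in rows.values()]
    )
    if bin_width is None:
        # modal width; ties break toward the larger (short terminal bins are rare)
        vals, counts = np.unique(widths, return_counts=True)
        bin_width = int(vals[counts == counts.max()].max())

    bins: dict[str, ChromBins] = {}
    for chrom, rr in rows.items():
        rr.sort()
        starts = np.array([s for s, _, _ in rr], dtype=np.int64)
        ends = np.array([e for _, e, _ in rr], dtype=np.int64)
        rate = np.array([r for _, _, r in rr], dtype=np.float64)
        if np.any(starts[1:] == starts[:-1]):
            i = int(np.flatnonzero(starts[1:] == starts[:-1])[0])
            raise MapFormatError(f"{chrom}: duplicate bin at start {starts[i]}")
        if np.any(ends[:-1] > starts[1:]):
            i = int(np.flatnonzero(ends[:-1] > starts[1:])[0])
            raise MapFormatError(f"{chrom}: overlapping bins at start {starts[i + 1]}")
        if np.any(starts % bin_width != 0):
            i = int(np.flatnonzero(starts % bin_width != 0)[0])
            raise MapFormatError(
                f"{chrom}: bin start {starts[i]} not aligned to {bin_width} bp grid"
            )
        w = ends - starts
        bad = w != bin_width
        if np.any(bad):
            # only a single short terminal bin is tolerated, and only if allowed
            ok = (
                dialect.allow_short_terminal
                and bad.sum() == 1
                and bad[-1]
                and w[-1] < bin_width
            )
            if not ok:
                i = int(np.flatnonzero(bad)[0])
                raise MapFormatError(
                    f"{chrom}: bin [{starts[i]},{ends[i]}) violates {bin_width} bp width"
                )
        bins[chrom] = ChromBins(starts=starts, ends=ends, rate=rate)

    return RecombinationMap(bins=dict(sorted(bins.items(), key=_chrom_key)), bin_width=bin_width)


def _chrom_key(item):
    name = item[0].removeprefix("chr")
    return (0, int(name)) if name.isdigit() else (1, name)


def standardize(rmap: RecombinationMap) -> RecombinationMap:
    """Divide every bin's rate by the genome-wide mean rate.

    The genome mean is the unweighted mean over all bins present (zeros
    included, missing bins excluded); since bins share one width this equals
    the length-weighted mean.  Idempotent: re-standardizing leaves SRR
    unchanged because the SRR mean is already 1.

    Raises
    ------
    ValueError
        If the map has no bins or an all-zero rate field (mean 0), for which
        standardization is undefined.
    """
    if rmap.n_bins == 0:
        raise ValueError("cannot standardize an empty map")
    mean = float(np.mean(rmap.all_rates()))
    if mean <= 0.0:
        raise ValueError("genome mean rate is 0; standardization undefined")
    new_bins = {
        c: ChromBins(cb.starts, cb.ends, cb.rate, srr=cb.rate / mean)
        for c, cb in rmap.bins.items()
    }
    out = replace(rmap, bins=new_bins, genome_mean_rate=mean)
    assert abs(float(np.mean(out.all_srr())) - 1.0) < MEAN_TOL
    return out


def srr_histogram(
    rmap: RecombinationMap,
    interval_edges=(0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0, np.inf),
    threshold: float = 2.0,
) -> SrrDistributionSummary:
    """Summarize the SRR distribution over half-open intervals.

    Each covered bin falls in exactly one interval [e_i, e_{i+1});
    ``fraction_zero`` counts bins with SRR exactly 0 and
    ``fraction_at_least_threshold`` those with SRR >= ``threshold``.
    """
    srr = rmap.all_srr()  # raises MapStateError if unstandardized
    edges = np.asarray(interval_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("interval_edges must be strictly increasing, length >= 2")
    if srr.min() < edges[0] or srr.max() >= edges[-1]:
        raise ValueError("interval_edges do not cover the SRR range")
    which = np.searchsorted(edges, srr, side="right") - 1
    counts = np.bincount(which, minlength=len(edges) - 1)
    n = len(srr)
    return SrrDistributionSummary(
        interval_edges=tuple(edges),
        bin_counts=tuple(int(c) for c in counts),
        fractions=tuple(float(c) / n for c in counts),
        fraction_zero=float(np.count_nonzero(srr == 0.0)) / n,
        fraction_below_one=float(np.count_nonzero(srr < 1.0)) / n,
        fraction_at_least_threshold=float(np.count_nonzero(srr >= threshold)) / n,
        threshold=float(threshold),
        n_bins=n,
    )


def write_srr_histogram(summary: SrrDistributionSummary, path) -> None:
    """Write interval_start, interval_end, count, fraction as TSV."""
    summary.to_frame().to_csv(path, sep="\t", index=False)
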