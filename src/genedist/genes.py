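"""Gene catalogues: reading refGene/BED tables and collapsing to one span per gene.

Transcript-level tables (UCSC refGene) carry several rows per gene symbol;
the extension algorithm wants exactly one interval per gene, so same-name
records on one chromosome are merged to their union span.  Coordinates are
0-based half-open internally; a 1-based dialect flag converts txStart-style
columns on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)


class GeneFormatError(ValueError):
    """Raised when a gene file fails parsing or validation."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """A named gene body. start/end are bp, 0-based half-open; start < end."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise GeneFormatError(
                f"gene {self.name}: degenerate interval [{self.start},{self.end})"
            )
        if not self.name:
            raise GeneFormatError("gene with empty name")
        if self.strand not in ("+", "-"):
            raise GeneFormatError(f"gene {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# UCSC refGene column order (bin column optional, detected by content)
_REFGENE_COLS = ("name", "chrom", "strand", "txStart", "txEnd")


def read_genes(
    path,
    format: str = "bed",
    one_based: bool = False,
    chrom_aliases: dict[str, str] | None = None,
) -> list[GeneRecord]:
    """Read a gene catalogue in ``bed`` (BED4/BED6) or ``refgene`` format.

    refGene rows are tab-delimited with at least name, chrom, strand,
    txStart, txEnd (a leading numeric UCSC ``bin`` column is tolerated).
    BED4 rows default to the + strand.  ``one_based`` converts 1-based
    inclusive starts to the internal 0-based half-open convention.
    ``chrom_aliases`` maps nonstandard chromosome names before validation.
    """
    if format not in ("bed", "refgene"):
        raise GeneFormatError(f"unknown gene format {format!r}; use 'bed' or 'refgene'")
    aliases = chrom_aliases or {}
    out: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "bed":
                    if len(parts) < 4:
                        raise ValueError("BED needs >= 4 columns")
                    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) >= 6 else "+"
                else:
                    # tolerate the leading UCSC bin column
                    if parts and parts[0].isdigit() and len(parts) >= 6:
                        parts = parts[1:]
                    if len(parts) < 5:
                        raise ValueError("refGene needs >= 5 columns")
                    name, chrom, strand = parts[0], parts[1], parts[2]
                    start, end = int(parts[3]), int(parts[4])
                if one_based:
                    start -= 1
                chrom = aliases.get(chrom, chrom)
                out.append(GeneRecord(chrom=chrom, start=start, end=end, name=name, strand=strand))
            except (ValueError, GeneFormatError) as exc:
                raise GeneFormatError(f"{path}:{lineno}: {exc}") from None
    return out


def collapse_transcripts(records: list[GeneRecord]) -> list[GeneRecord]:
    """Merge same-name records on one chromosome to their union span.

    Idempotent and order-independent.  A name appearing on several
    chromosomes is kept as separate genes with ``_chrom``-suffixed names
    (and a logged warning), since a single span would be meaningless.
    Overlapping *distinct* genes are left untouched: units may overlap.
    """
    by_name: dict[str, dict[str, list[GeneRecord]]] = {}
    for rec in records:
        by_name.setdefault(rec.name, {}).setdefault(rec.chrom, []).append(rec)

    out: list[GeneRecord] = []
    for name, per_chrom in by_name.items():
        multi = len(per_chrom) > 1
        if multi:
            logger.warning(
                "gene %s appears on chromosomes %s; keeping separate suffixed records",
                name, sorted(per_chrom),
            )
        for chrom, recs in per_chrom.items():
            merged = replace(
                recs[0],
                start=min(r.start for r in recs),
                end=max(r.end for r in recs),
                name=f"{name}_{chrom}" if multi else name,
            )
            out.append(merged)
    out.sort()
    return out
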