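"""Shared record types used across the pipeline.

Internal coordinates are 0-based half-open throughout the package; the I/O
layer converts to/from the 1-based inclusive conventions of GFF3 and VCF at
the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CHROM_CLASSES = ("A", "X", "Y", "SHORT", "UNASSIGNED")


@dataclass(frozen=True)
class ContigRecord:
    """A contig with its chromosome-class label."""

    id: str
    length: int
    chrom_class: str = "UNASSIGNED"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: length must be positive")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"contig {self.id}: unknown class {self.chrom_class!r}")


@dataclass
class GeneModel:
    """A gene with one transcript; exons ordered 5'->3' on the genome."""

    gene_id: str
    transcript_id: str
    contig: str
    start: int            # 0-based
    end: int              # half-open
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")

    def cds(self, contig_seq: str) -> str:
        """Spliced coding sequence in transcript orientation."""
        from .align import revcomp

        parts = [contig_seq[s:e] for s, e in sorted(self.exons)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class HomologyHit:
    """A filtered similarity hit of a Y transcript against the genome."""

    query: str
    subject: str
    percent_identity: float      # 0-100
    query_coverage: float        # 0-1
    bit_score: float
    evalue: float | None = None  # absent for the internal aligner
    subject_class: str | None = None

    def __post_init__(self) -> None:
        if self.query == self.subject:
            raise ValueError(f"self match {self.query} must be excluded upstream")


@dataclass
class VariantSite:
    """One biallelic site with per-line genotype and depth.

    ``gt`` maps sample name to an allele-index pair (or None if missing);
    ``dp`` maps sample name to read depth (or None).
    """

    contig: str
    pos: int                  # 0-based internally
    ref: str
    alt: str
    gt: dict[str, tuple[int, int] | None]
    dp: dict[str, int | None]
    category: str = "UNCATEGORIZED"
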