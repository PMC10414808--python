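"""Tandem copy-number detection and exon-presence profiling of a probe gene.

Given the exon set of a full-length probe gene (typically its complete
autosomal copy), every exon is aligned against a haplotype contig on both
strands; exon hits are clustered along the contig into copy units, and each
unit reports a per-exon status — present, partial (20–80% of the exon
aligned) or absent.  Truncated Y-linked copies therefore show up with their
5'-most exons absent and the breakpoint exon partial, and the tandem unit
count is the copy number of the region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .align import LocalHit, SeedIndex, search

__all__ = ["CnvCall", "CopyUnit", "RegionComparison", "detect_tandem_copies", "compare_regions"]


@dataclass
class CopyUnit:
    start: int
    end: int
    orientation: str
    exon_status: dict[int, str]          # exon index (0-based, probe order) -> status
    exon_aligned_fraction: dict[int, float]
    exon_identity: dict[int, float]

    @property
    def n_detected(self) -> int:
        return sum(1 for v in self.exon_status.values() if v != "absent")

    def mean_exon_identity(self) -> float | None:
        vals = [v for k, v in self.exon_identity.items() if self.exon_status[k] != "absent"]
        return sum(vals) / len(vals) if vals else None


@dataclass
class CnvCall:
    contig: str
    copy_count: int
    copies: list[CopyUnit] = field(default_factory=list)

    def exon_profile(self, n_exons: int) -> list[list[str]]:
        """Per-copy status list over the probe's exon numbering."""
        return [
            [c.exon_status.get(i, "absent") for i in range(n_exons)] for c in self.copies
        ]


def detect_tandem_copies(
    contig_seq: str,
    probe_exons: list[str],
    contig_id: str = "contig",
    max_intra_copy_gap: int = 50_000,
    min_exons: int = 3,
    present_min: float = 0.8,
    partial_min: float = 0.2,
    min_hit_identity: float = 80.0,
    min_score: float = 40.0,
) -> CnvCall:
    """Count tandem copies of the probe gene in a contig.

    ``probe_exons`` are the exon sequences ordered 5'->3' on the probe.
    Exon hits are sorted by contig position and grouped into copy units: a
    new unit starts when the gap to the previous hit exceeds
    ``max_intra_copy_gap``, the orientation flips, or the exon order resets
    (an earlier exon following a later one, which marks the next tandem
    copy).  Units with at least ``min_exons`` non-absent exons count as
    copies; statuses derive from each exon's aligned query fraction
    (>= ``present_min`` present, >= ``partial_min`` partial, else absent).
    Copies are reported 5'->3' on the contig.
    """
    if not probe_exons:
        raise ValueError("probe exon set is empty")
    total_probe = sum(len(e) for e in probe_exons)
    if total_probe > len(contig_seq):
        warnings.warn(
            f"probe ({total_probe} bp) longer than contig {contig_id} "
            f"({len(contig_seq)} bp); reporting 0 copies",
            stacklevel=2,
        )
        return CnvCall(contig=contig_id, copy_count=0)
    index = SeedIndex(contig_seq, "nucleotide")
    all_hits: list[tuple[int, LocalHit]] = []  # (exon idx, hit)
    for i, exon in enumerate(probe_exons):
        for h in search(exon, index, both_strands=True, min_score=min_score):
            if h.percent_identity >= min_hit_identity:
                all_hits.append((i, h))
    all_hits.sort(key=lambda ih: (ih[1].s_start, ih[1].s_end))

    units: list[list[tuple[int, LocalHit]]] = []
    for i, h in all_hits:
        if units:
            pj, ph = units[-1][-1]
            same = (
                h.s_start - ph.s_end <= max_intra_copy_gap
                and h.strand == ph.strand
                and ((h.strand == "+" and i > pj) or (h.strand == "-" and i < pj))
            )
            if same:
                units[-1].append((i, h))
                continue
        units.append([(i, h)])

    copies: list[CopyUnit] = []
    for unit in units:
        best: dict[int, LocalHit] = {}
        for i, h in unit:
            if i not in best or h.raw_score > best[i].raw_score:
                best[i] = h
        status, frac, ident = {}, {}, {}
        for i in range(len(probe_exons)):
            h = best.get(i)
            f = h.query_coverage if h is not None else 0.0
            frac[i] = f
            ident[i] = h.percent_identity if h is not None else 0.0
            status[i] = "present" if f >= present_min else "partial" if f >= partial_min else "absent"
        cu = CopyUnit(
            start=min(h.s_start for _, h in unit),
            end=max(h.s_end for _, h in unit),
            orientation=unit[0][1].strand,
            exon_status=status,
            exon_aligned_fraction=frac,
            exon_identity=ident,
        )
        if cu.n_detected >= min_exons:
            copies.append(cu)
    copies.sort(key=lambda c: c.start)
    return CnvCall(contig=contig_id, copy_count=len(copies), copies=copies)


# ---------------------------------------------------------------------------
# exonic vs noncoding divergence


@dataclass
class RegionComparison:
    """Identity of two gene regions measured on disjoint sequence masks."""

    exonic_identity: float | None        # percent, None when undefined
    noncoding_identity: float | None
    exonic_aligned_fraction: float | None
    noncoding_aligned_fraction: float | None
    unaligned_gap_count: int


def _mask(seq: str, intervals: list[tuple[int, int]], keep: bool) -> str:
    """Hard-mask with N; ``keep=True`` retains the intervals, masking the rest."""
    arr = bytearray(seq.encode("ascii"))
    inside = bytearray(len(arr))
    for s, e in intervals:
        if not 0 <= s <= e <= len(arr):
            raise ValueError(f"mask interval ({s},{e}) outside sequence of length {len(arr)}")
        for i in range(s, e):
            inside[i] = 1
    for i in range(len(arr)):
        if bool(inside[i]) != keep:
            arr[i] = ord("N")
    return arr.decode("ascii")


def _unmasked_runs(seq: str, min_len: int = 20) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c != "N" and start is None:
            start = i
        elif c == "N" and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_len:
        runs.append((start, len(seq)))
    return runs


def _component(
    seq_a: str, seq_b: str, min_score: float
) -> tuple[float | None, float | None, int]:
    """Align each unmasked run of A against masked B; aggregate.

    Hard masking splits a region into separate blocks (each exon, each
    intervening noncoding stretch), so blocks are queried one by one and
    the best alignment of each contributes to the pooled identity.  Blocks
    with no alignment at all are the reported unaligned gaps.
    """
    runs = _unmasked_runs(seq_a)
    if not runs or set(seq_b) <= {"N"}:
        return None, None, 0
    idx = SeedIndex(seq_b, "nucleotide")
    unmasked = sum(e - s for s, e in runs)
    matches = columns = covered = gaps = 0
    for s, e in runs:
        hits = search(seq_a[s:e], idx, both_strands=True, min_score=min_score)
        if not hits:
            gaps += 1
            continue
        best = max(hits, key=lambda h: h.raw_score)
        matches += best.n_matches
        columns += best.aln_columns
        covered += best.q_end - best.q_start
    if columns == 0:
        return 0.0, 0.0, gaps
    return 100.0 * matches / columns, covered / unmasked, gaps


def compare_regions(
    seq_a: str,
    exons_a: list[tuple[int, int]],
    seq_b: str,
    exons_b: list[tuple[int, int]],
    min_score: float = 40.0,
) -> RegionComparison:
    """Align exonic and noncoding portions of two regions separately.

    Two alignments are run on complementary hard-masked inputs: once with
    everything but the exons masked, once with the exons masked.  Identity
    and the fraction of region A's unmasked sequence covered by alignments
    are reported per component; a fully masked component is undefined
    (None), not zero.
    """
    exonic = _component(_mask(seq_a, exons_a, True), _mask(seq_b, exons_b, True), min_score)
    noncod = _component(_mask(seq_a, exons_a, False), _mask(seq_b, exons_b, False), min_score)
    return RegionComparison(
        exonic_identity=exonic[0],
        noncoding_identity=noncod[0],
        exonic_aligned_fraction=exonic[1],
        noncoding_aligned_fraction=noncod[1],
        unaligned_gap_count=(exonic[2] or 0) + (noncod[2] or 0),
    )
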