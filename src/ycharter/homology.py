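"""Origin classification of Y transcripts and ampliconic group detection.

A Y-linked gene can descend from the ancestral proto-sex chromosome (an X
*gametolog* survives), from an autosome-to-Y translocation (an autosomal
*paralog* exists), or both.  Hits of each Y protein against all proteins of
the assembly are filtered (query coverage > 50%, identity > 80%, E-value
<= 1e-20 when the hit table carries E-values, otherwise a bit-score floor)
and the surviving subjects' contig classes decide the category.  Any
qualifying hit on a sub-100 kb contig makes the transcript uncategorizable,
since that contig's class is unknown.

Ampliconic genes are Y genes present in multiple near-identical copies:
all-vs-all comparison of concatenated CDS per transcript, an undirected
edge for every pair passing >95% query coverage and >99.9% identity in
either direction, and connected components of size >= 2 as groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .align import SeedIndex, search
from .exact_stats import EnrichmentResult, TwoByTwo, fisher_exact
from .models import HomologyHit

__all__ = [
    "OriginCall",
    "AmpliconGroup",
    "classify_origins",
    "detect_amplicon_groups",
    "amplicon_accounting",
    "all_vs_all_hits",
    "gametolog_enrichment_test",
    "homolog_count_correlation",
]

ORIGIN_CATEGORIES = (
    "EXCLUSIVE_X",
    "EXCLUSIVE_A",
    "BOTH",
    "EXCLUDED_UNCATEGORIZED",
    "NO_HOMOLOG",
)


@dataclass
class OriginCall:
    transcript: str
    category: str
    n_x_hits: int
    n_a_hits: int


@dataclass
class AmpliconGroup:
    members: tuple[str, ...]
    representative: str


def classify_origins(
    hits: list[HomologyHit],
    transcripts: list[str],
    min_qcov: float = 0.50,
    min_identity: float = 80.0,
    max_evalue: float = 1e-20,
    min_bitscore: float = 50.0,
) -> tuple[dict[str, OriginCall], dict[str, int]]:
    """Assign each Y transcript an origin category from its filtered hits.

    ``transcripts`` lists every Y transcript so that those with no
    qualifying hit are reported as NO_HOMOLOG.  A hit qualifies when query
    coverage and identity exceed the thresholds and its E-value is at most
    ``max_evalue``; hits without E-values (internal aligner) must instead
    reach ``min_bitscore``.  Returns per-transcript calls and category
    counts.
    """
    per_tx: dict[str, dict[str, int]] = {
        t: {"X": 0, "A": 0, "SHORT": 0, "Y": 0} for t in transcripts
    }
    for h in hits:
        if h.query not in per_tx:
            continue
        if h.subject_class is None:
            raise ValueError(f"hit {h.query} -> {h.subject}: subject contig class unlabeled")
        if h.query_coverage <= min_qcov or h.percent_identity <= min_identity:
            continue
        if h.evalue is not None:
            if h.evalue > max_evalue:
                continue
        elif h.bit_score < min_bitscore:
            continue
        per_tx[h.query][h.subject_class] += 1
    calls: dict[str, OriginCall] = {}
    for t, counts in per_tx.items():
        if counts["SHORT"] > 0:
            cat = "EXCLUDED_UNCATEGORIZED"
        elif counts["X"] > 0 and counts["A"] > 0:
            cat = "BOTH"
        elif counts["X"] > 0:
            cat = "EXCLUSIVE_X"
        elif counts["A"] > 0:
            cat = "EXCLUSIVE_A"
        else:
            cat = "NO_HOMOLOG"
        calls[t] = OriginCall(
            transcript=t, category=cat, n_x_hits=counts["X"], n_a_hits=counts["A"]
        )
    summary = {c: 0 for c in ORIGIN_CATEGORIES}
    for call in calls.values():
        summary[call.category] += 1
    return calls, summary


def all_vs_all_hits(
    queries: dict[str, str],
    subjects: dict[str, str],
    subject_classes: dict[str, str],
    mode: str = "protein",
    min_score: float = 30.0,
) -> list[HomologyHit]:
    """Align every query against every subject with the internal aligner.

    Self matches (same id) are excluded.  Subjects are indexed once each.
    """
    indexes = {name: SeedIndex(seq, mode) for name, seq in subjects.items()}
    hits: list[HomologyHit] = []
    for q_name, q_seq in queries.items():
        for s_name, idx in indexes.items():
            if s_name == q_name:
                continue
            found = search(q_seq, idx, min_score=min_score)
            if not found:
                continue
            best = max(found, key=lambda h: h.raw_score)
            hits.append(
                HomologyHit(
                    query=q_name,
                    subject=s_name,
                    percent_identity=best.percent_identity,
                    query_coverage=best.query_coverage,
                    bit_score=best.bit_score,
                    evalue=None,
                    subject_class=subject_classes.get(s_name),
                )
            )
    return hits


def detect_amplicon_groups(
    cds: dict[str, str],
    min_qcov: float = 0.95,
    min_identity: float = 99.9,
    min_score: float = 30.0,
) -> tuple[list[AmpliconGroup], dict[str, int]]:
    """Find groups of near-identical Y transcripts.

    ``cds`` maps transcript id to its concatenated CDS.  A pair is joined
    when the alignment passes both thresholds in either query->subject
    direction (coverage is asymmetric in length-discordant pairs).  The
    representative of a group is its longest member, ties broken
    lexicographically.  Returns the groups and the accounting summary
    (total, ampliconic, n_groups, unique).
    """
    ids = list(cds)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate transcript ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    indexes = {name: SeedIndex(seq, "nucleotide") for name, seq in cds.items()}
    for i, qi in enumerate(ids):
        for sj in ids[i + 1 :]:
            joined = False
            for a, b in ((qi, sj), (sj, qi)):
                found = search(cds[a], indexes[b], min_score=min_score)
                if not found:
                    continue
                best = max(found, key=lambda h: h.raw_score)
                if best.query_coverage > min_qcov and best.percent_identity > min_identity:
                    joined = True
                    break
            if joined:
                g.add_edge(qi, sj)
    groups = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = tuple(sorted(comp))
        rep = min(members, key=lambda t: (-len(cds[t]), t))
        groups.append(AmpliconGroup(members=members, representative=rep))
    groups.sort(key=lambda gr: gr.members)
    ampliconic = sum(len(gr.members) for gr in groups)
    summary = dict(
        total=len(ids),
        ampliconic=ampliconic,
        n_groups=len(groups),
        unique=amplicon_accounting(len(ids), ampliconic, len(groups)),
    )
    return groups, summary


def amplicon_accounting(total: int, ampliconic: int, n_groups: int) -> int:
    """Unique transcripts: non-ampliconic ones plus one per ampliconic group."""
    if not 0 <= n_groups <= ampliconic <= total:
        raise ValueError("need 0 <= n_groups <= ampliconic <= total")
    if ampliconic > 0 and n_groups == 0:
        raise ValueError("ampliconic transcripts imply at least one group")
    return total - ampliconic + n_groups


def gametolog_enrichment_test(
    n_exclusive_x: int,
    n_exclusive_a: int,
    x_size: int,
    a_size: int,
    conf_level: float = 0.95,
) -> EnrichmentResult:
    """Exact test of X-gametolog vs autosomal-paralog density.

    ``x_size``/``a_size`` may be chromosome-class lengths in bp or total
    transcript counts; each class contributes the row
    ``[count, size - count]``.
    """
    if n_exclusive_x > x_size or n_exclusive_a > a_size:
        raise ValueError("counts cannot exceed class sizes")
    table = TwoByTwo(
        n_exclusive_x, x_size - n_exclusive_x, n_exclusive_a, a_size - n_exclusive_a
    )
    return fisher_exact(table, conf_level=conf_level)


def homolog_count_correlation(
    n_x_hits: np.ndarray | list[int], n_a_hits: np.ndarray | list[int]
) -> tuple[float, float, int]:
    """Pearson correlation of per-transcript X vs autosomal homolog counts.

    Applies to transcripts with hits on both; returns (r, t, df) with
    t = r * sqrt(df) / sqrt(1 - r^2), df = n - 2.
    """
    x = np.asarray(n_x_hits, dtype=float)
    a = np.asarray(n_a_hits, dtype=float)
    if x.shape != a.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 transcripts")
    r = float(stats.pearsonr(x, a).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return r, float(t), df
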