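"""Origin classification, amplicon grouping and the enrichment statistics."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from ycharter.homology import (
    amplicon_accounting,
    all_vs_all_hits,
    classify_origins,
    detect_amplicon_groups,
    gametolog_enrichment_test,
    homolog_count_correlation,
)
from ycharter.models import HomologyHit

from .conftest import rng_seq


def _hit(q, s, ident=95.0, qcov=0.9, cls="X", evalue=1e-30, bits=200.0):
    return HomologyHit(query=q, subject=s, percent_identity=ident,
                       query_coverage=qcov, bit_score=bits, evalue=evalue,
                       subject_class=cls)


def test_single_x_hit_is_exclusive_gametolog():
    calls, summary = classify_origins([_hit("y1", "x1")], ["y1"])
    assert calls["y1"].category == "EXCLUSIVE_X"
    assert summary["EXCLUSIVE_X"] == 1


def test_short_contig_hit_excludes_regardless_of_others():
    hits = [_hit("y1", "x1", cls="X"), _hit("y1", "a1", cls="A"),
            _hit("y1", "s1", cls="SHORT")]
    calls, _ = classify_origins(hits, ["y1"])
    assert calls["y1"].category == "EXCLUDED_UNCATEGORIZED"


def test_no_hit_transcripts_reported():
    calls, summary = classify_origins([], ["y1", "y2"])
    assert {c.category for c in calls.values()} == {"NO_HOMOLOG"}
    assert summary["NO_HOMOLOG"] == 2


def test_unlabeled_subject_contig_rejected():
    bad = _hit("y1", "x1")
    bad.subject_class = None
    with pytest.raises(ValueError, match="unlabeled"):
        classify_origins([bad], ["y1"])


def test_categories_match_independent_filter_oracle():
    """Randomized hit tables: categories equal a brute-force re-derivation."""
    rng = np.random.default_rng(8)
    classes = ["X", "A", "SHORT", "Y"]
    for _ in range(60):
        tx = [f"y{i}" for i in range(rng.integers(1, 6))]
        hits = []
        for q in tx:
            for j in range(rng.integers(0, 6)):
                hits.append(HomologyHit(
                    query=q, subject=f"s{j}",
                    percent_identity=float(rng.uniform(60, 100)),
                    query_coverage=float(rng.uniform(0.2, 1.0)),
                    bit_score=float(rng.uniform(20, 300)),
                    evalue=float(10.0 ** rng.uniform(-40, -5)),
                    subject_class=str(rng.choice(classes)),
                ))
        calls, _ = classify_origins(hits, tx)
        for q in tx:
            kept = [h for h in hits if h.query == q
                    and h.query_coverage > 0.50
                    and h.percent_identity > 80.0
                    and h.evalue <= 1e-20]
            short = any(h.subject_class == "SHORT" for h in kept)
            nx = sum(h.subject_class == "X" for h in kept)
            na = sum(h.subject_class == "A" for h in kept)
            expected = (
                "EXCLUDED_UNCATEGORIZED" if short
                else "BOTH" if nx and na
                else "EXCLUSIVE_X" if nx
                else "EXCLUSIVE_A" if na
                else "NO_HOMOLOG"
            )
            assert calls[q].category == expected


def test_categories_mutually_exclusive_and_exhaustive(small_sim):
    """Planted origins are recovered exactly on the synthetic genome."""
    truth, assembly = small_sim["truth"], small_sim["assembly"]
    genes = {g.transcript_id: g for g in small_sim["annotation"]}
    proteins = {}
    for tid, g in genes.items():
        cds = g.cds(assembly[g.contig])
        proteins[tid] = str(Seq(cds[: len(cds) - len(cds) % 3]).translate()).rstrip("*")
    y_tx = sorted(truth.gene_origins)
    classes = {tid: truth.contig_classes[g.contig] for tid, g in genes.items()}
    hits = all_vs_all_hits({t: proteins[t] for t in y_tx}, proteins, classes)
    calls, summary = classify_origins(hits, y_tx)
    assert sum(summary.values()) == len(y_tx)
    for tid in y_tx:
        assert calls[tid].category == truth.gene_origins[tid], tid


# --- amplicons ---------------------------------------------------------------


def _family(rng, base, n, identity=0.9995):
    out = [base]
    L = len(base)
    k = max(1, round((1 - identity) * L))
    for _ in range(n - 1):
        arr = list(base)
        for i in rng.choice(L, size=k, replace=False):
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        out.append("".join(arr))
    return out


def test_no_close_pairs_means_no_groups():
    rng = np.random.default_rng(10)
    cds = {f"t{i}": rng_seq(rng, 600) for i in range(5)}
    groups, summary = detect_amplicon_groups(cds)
    assert groups == []
    assert summary["unique"] == summary["total"] == 5


def test_planted_families_recovered_exactly():
    rng = np.random.default_rng(11)
    a, b, c = _family(rng, rng_seq(rng, 2000), 3)
    d, e = _family(rng, rng_seq(rng, 2000), 2)
    f = rng_seq(rng, 2000)
    cds = dict(A=a, B=b, C=c, D=d, E=e, F=f)
    groups, summary = detect_amplicon_groups(cds)
    assert [set(g.members) for g in groups] == [{"A", "B", "C"}, {"D", "E"}]
    assert summary == dict(total=6, ampliconic=5, n_groups=2, unique=3)


def test_grouping_invariant_under_input_permutation():
    rng = np.random.default_rng(12)
    a, b = _family(rng, rng_seq(rng, 700), 2)
    cds = dict(A=a, B=b, C=rng_seq(rng, 700))
    results = []
    for perm in itertools.permutations(cds):
        groups, _ = detect_amplicon_groups({k: cds[k] for k in perm})
        results.append([g.members for g in groups])
    assert all(r == results[0] for r in results)


def test_synthetic_families_recovered(small_sim):
    truth, assembly = small_sim["truth"], small_sim["assembly"]
    y_cds = {
        g.transcript_id: g.cds(assembly[g.contig])
        for g in small_sim["annotation"]
        if truth.contig_classes[g.contig] == "Y"
    }
    groups, summary = detect_amplicon_groups(y_cds)
    expected = {frozenset(m) for m in truth.amplicon_families.values()}
    assert {frozenset(g.members) for g in groups} == expected
    assert summary["unique"] == summary["total"] - summary["ampliconic"] + summary["n_groups"]


def test_inconsistent_accounting_rejected():
    with pytest.raises(ValueError):
        amplicon_accounting(10, 11, 2)
    with pytest.raises(ValueError):
        amplicon_accounting(10, 5, 0)


def test_accounting_identity_randomized():
    rng = np.random.default_rng(13)
    for _ in range(1000):
        total = int(rng.integers(1, 500))
        ampliconic = int(rng.integers(0, total + 1))
        n_groups = int(rng.integers(1, ampliconic + 1)) if ampliconic else 0
        n_groups = min(n_groups, ampliconic // 2) if ampliconic >= 2 else (
            0 if ampliconic == 0 else 1)
        if ampliconic == 1:
            ampliconic = 0
            n_groups = 0
        unique = amplicon_accounting(total, ampliconic, n_groups)
        assert unique == total - ampliconic + n_groups
        assert 0 <= unique <= total


# --- enrichment + correlation ------------------------------------------------


def test_equal_densities_ci_contains_one():
    r = gametolog_enrichment_test(10, 10, 10**6, 10**6)
    assert r.ci_low < 1.0 < r.ci_high
    assert r.p_two_sided == pytest.approx(1.0)


def test_counts_cannot_exceed_sizes():
    with pytest.raises(ValueError, match="exceed"):
        gametolog_enrichment_test(11, 1, 10, 100)


def test_perfectly_proportional_counts_r_one():
    x = np.arange(1, 20)
    r, t, df = homolog_count_correlation(x, 3 * x)
    assert r == pytest.approx(1.0)
    assert t == np.inf and df == 17


def test_uncorrelated_counts_t_near_zero():
    rng = np.random.default_rng(14)
    x, y = rng.poisson(5, 400), rng.poisson(5, 400)
    r, t, df = homolog_count_correlation(x, y)
    assert abs(t) < 2.5


def test_planted_correlation_recovered():
    """Mean recovered r within 0.1 of the planted 0.6 over 200 replicates."""
    rng = np.random.default_rng(15)
    rho = 0.6
    rs = []
    for _ in range(200):
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=115)
        r, _, _ = homolog_count_correlation(z[:, 0], z[:, 1])
        rs.append(r)
    assert abs(np.mean(rs) - rho) < 0.1


def test_too_few_transcripts_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        homolog_count_correlation([1, 2], [2, 4])
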