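"""Tandem copy detection, exon profiles and exonic/noncoding comparison."""

import numpy as np
import pytest

from ycharter.cnv import compare_regions, detect_tandem_copies
from ycharter.models import GeneModel

from .conftest import rng_seq, small_config
from ycharter.simulate import simulate_genome


def _probe(rng, n_exons=8, exon_len=150, intron_len=200):
    exons = [rng_seq(rng, exon_len) for _ in range(n_exons)]
    gene = ""
    intervals = []
    pos = 0
    for i, e in enumerate(exons):
        intervals.append((pos, pos + len(e)))
        gene += e
        pos += len(e)
        if i < n_exons - 1:
            gene += rng_seq(rng, intron_len)
            pos += intron_len
    return exons, gene, intervals


def test_absent_probe_reports_zero_copies():
    rng = np.random.default_rng(30)
    exons, _, _ = _probe(rng)
    call = detect_tandem_copies(rng_seq(rng, 20_000), exons)
    assert call.copy_count == 0


def test_probe_longer_than_contig_warns_not_errors():
    rng = np.random.default_rng(31)
    exons, _, _ = _probe(rng)
    with pytest.warns(UserWarning, match="longer than contig"):
        call = detect_tandem_copies(rng_seq(rng, 100), exons)
    assert call.copy_count == 0


def test_single_exact_insertion_all_exons_present():
    rng = np.random.default_rng(32)
    exons, gene, _ = _probe(rng)
    contig = rng_seq(rng, 3_000) + gene + rng_seq(rng, 3_000)
    call = detect_tandem_copies(contig, exons)
    assert call.copy_count == 1
    assert set(call.copies[0].exon_status.values()) == {"present"}
    assert call.copies[0].orientation == "+"


def test_reverse_orientation_copy_detected():
    from ycharter.align import revcomp

    rng = np.random.default_rng(33)
    exons, gene, _ = _probe(rng)
    contig = rng_seq(rng, 2_000) + revcomp(gene) + rng_seq(rng, 2_000)
    call = detect_tandem_copies(contig, exons)
    assert call.copy_count == 1
    assert call.copies[0].orientation == "-"
    assert set(call.copies[0].exon_status.values()) == {"present"}


def test_exon_status_translation_invariant():
    rng = np.random.default_rng(34)
    exons, gene, _ = _probe(rng)
    truncated = gene[2 * 150 + 2 * 200 + 75 :]  # drop 2 exons + half of the third
    profiles = []
    for offset in (500, 9_000):
        contig = rng_seq(rng, offset) + truncated + rng_seq(rng, 12_000 - offset)
        call = detect_tandem_copies(contig, exons)
        assert call.copy_count == 1
        profiles.append([call.copies[0].exon_status[i] for i in range(len(exons))])
    assert profiles[0] == profiles[1]
    assert profiles[0][:2] == ["absent", "absent"]
    assert profiles[0][2] == "partial"
    assert set(profiles[0][3:]) == {"present"}


def test_tandem_copies_with_divergence_counted_exactly():
    rng = np.random.default_rng(35)
    exons, gene, _ = _probe(rng)

    def mutate(seq, rate=0.01):
        arr = list(seq)
        for i in rng.choice(len(arr), size=int(rate * len(arr)), replace=False):
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        return "".join(arr)

    for k in (2, 4):
        contig = rng_seq(rng, 2_000)
        for _ in range(k):
            contig += mutate(gene) + rng_seq(rng, 1_500)
        call = detect_tandem_copies(contig + rng_seq(rng, 500), exons)
        assert call.copy_count == k
        starts = [c.start for c in call.copies]
        assert starts == sorted(starts)


def test_synthetic_haplotypes_mirror_planted_cnv(small_sim):
    """3 truncated tandem copies on Y_S, 1 on Y_L; exon profile as planted."""
    cfg = small_sim["cfg"]
    assembly, truth = small_sim["assembly"], small_sim["truth"]
    probe = next(g for g in small_sim["annotation"] if g.gene_id == "CAND_A")
    contig_seq = assembly[probe.contig]
    exon_seqs = [contig_seq[s:e] for s, e in sorted(probe.exons)]
    for hap, contig in (("S", "Y_S"), ("L", "Y_L")):
        call = detect_tandem_copies(assembly[contig], exon_seqs, contig_id=contig)
        planted = truth.candidate_copies[hap]
        assert call.copy_count == len(planted)
        for copy, tr in zip(call.copies, planted):
            got = [copy.exon_status[i] for i in range(cfg.candidate_exons)]
            assert got == tr["exon_status"]
            # coordinates agree to within the missing flanks
            assert abs(copy.start - tr["start"]) < 200
            assert abs(copy.end - tr["end"]) < 5_000  # truth block includes spacer


def test_empty_probe_rejected():
    with pytest.raises(ValueError, match="empty"):
        detect_tandem_copies("ACGT" * 100, [])


# --- region comparison -------------------------------------------------------


def test_identical_regions_identity_100():
    rng = np.random.default_rng(36)
    _, gene, intervals = _probe(rng)
    r = compare_regions(gene, intervals, gene, intervals)
    assert r.exonic_identity == pytest.approx(100.0)
    assert r.noncoding_identity == pytest.approx(100.0)
    assert r.exonic_aligned_fraction == pytest.approx(1.0, abs=0.02)


def test_planted_noncoding_divergence_measured_separately():
    rng = np.random.default_rng(37)
    exons, gene, intervals = _probe(rng, n_exons=6, exon_len=200, intron_len=400)
    arr = list(gene)
    exonic = np.zeros(len(arr), bool)
    for s, e in intervals:
        exonic[s:e] = True
    introns = np.flatnonzero(~exonic)
    for i in rng.choice(introns, size=int(0.05 * len(introns)), replace=False):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    diverged = "".join(arr)
    r = compare_regions(gene, intervals, diverged, intervals)
    assert r.exonic_identity == pytest.approx(100.0)
    assert r.noncoding_identity == pytest.approx(95.0, abs=1.5)
    assert r.noncoding_identity < r.exonic_identity


def test_fully_masked_component_is_undefined():
    rng = np.random.default_rng(38)
    seq = rng_seq(rng, 1_000)
    r = compare_regions(seq, [], seq, [])  # no exons at all
    assert r.exonic_identity is None
    assert r.noncoding_identity == pytest.approx(100.0)


def test_synthetic_autosome_vs_y_noncoding_divergence(small_sim):
    """Introns diverge more than exons between autosomal and Y copies."""
    assembly, truth = small_sim["assembly"], small_sim["truth"]
    probe = next(g for g in small_sim["annotation"] if g.gene_id == "CAND_A")
    a_seq = assembly[probe.contig][probe.start:probe.end]
    a_exons = [(s - probe.start, e - probe.start) for s, e in probe.exons]
    ycopy = next(g for g in small_sim["annotation"] if g.gene_id == "CANDY1")
    y_seq = assembly["Y_S"][ycopy.start:ycopy.end]
    y_exons = [(s - ycopy.start, e - ycopy.start) for s, e in ycopy.exons]
    r = compare_regions(y_seq, y_exons, a_seq, a_exons)
    assert r.exonic_identity is not None and r.noncoding_identity is not None
    assert r.noncoding_identity < r.exonic_identity
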