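"""Depth filtering, SNP/SNV partitioning, density tests and cis annotation."""

import numpy as np
import pytest

from ycharter.models import GeneModel, VariantSite
from ycharter.variants import (
    annotate_cis_proximity,
    density_enrichment,
    density_table,
    filter_sites,
    partition_variants,
)


def _site(contig="Y", pos=100, ref="A", alt="G", gt1=(0, 1), gt2=(0, 1),
          dp1=30, dp2=30):
    return VariantSite(contig=contig, pos=pos, ref=ref, alt=alt,
                       gt={"LINE_S": gt1, "LINE_L": gt2},
                       dp={"LINE_S": dp1, "LINE_L": dp2})


@pytest.mark.parametrize("dp, kept", [
    ((5, 65), True),    # bounds inclusive
    ((4, 30), False),
    ((30, 66), False),
    ((5, 5), True),
    ((65, 65), True),
])
def test_depth_bounds_inclusive(dp, kept):
    retained, _ = filter_sites([_site(dp1=dp[0], dp2=dp[1])])
    assert bool(retained) is kept


def test_filter_counts_by_reason():
    sites = [
        _site(),
        _site(dp1=None),
        _site(dp2=2),
        _site(alt="GT"),
    ]
    retained, dropped = filter_sites(sites)
    assert len(retained) == 1
    assert dropped == {"not_snv": 1, "no_depth": 1, "depth_out_of_range": 1}
    assert sites[1].category == "FILTERED"


def test_constructed_fixture_80_of_100_retained():
    rng = np.random.default_rng(20)
    sites = [_site(pos=i, dp1=30, dp2=30) for i in range(80)]
    sites += [_site(pos=100 + i, dp1=int(rng.integers(0, 5)), dp2=30) for i in range(20)]
    retained, dropped = filter_sites(sites)
    assert len(retained) == 80
    assert dropped["depth_out_of_range"] == 20


@pytest.mark.parametrize("gt1, gt2, expected", [
    ((1, 1), (0, 0), "FIXED_SNV"),
    ((0, 0), (1, 1), "FIXED_SNV"),
    ((0, 1), (0, 1), "SHARED_SNP"),
    ((0, 1), (0, 0), "OTHER"),
    ((0, 0), (0, 0), "OTHER"),
    (None, (0, 1), "OTHER"),
])
def test_partition_definitions(gt1, gt2, expected):
    sites, counts = partition_variants([_site(gt1=gt1, gt2=gt2)])
    assert sites[0].category == expected
    assert counts[expected] == 1


def test_allele_presence_semantics():
    s = _site(gt1=(0, 1), gt2=(1, 1))
    assert partition_variants([s], "het_in_both")[0][0].category == "OTHER"
    # one line het, the other hom-alt: both alleles are NOT seen in line 2
    assert partition_variants([_site(gt1=(0, 1), gt2=(1, 1))],
                              "allele_in_both")[0][0].category == "OTHER"
    # both lines het: both alleles seen in both lines under either semantics
    assert partition_variants([_site()], "allele_in_both")[0][0].category == "SHARED_SNP"


def test_more_than_two_samples_rejected():
    s = _site()
    s.gt["LINE_X"] = (0, 1)
    with pytest.raises(ValueError, match="two line samples"):
        partition_variants([s])


def test_partition_is_exhaustive_random_genotypes():
    rng = np.random.default_rng(21)
    gts = [None, (0, 0), (0, 1), (1, 1)]
    sites = [_site(gt1=gts[rng.integers(4)], gt2=gts[rng.integers(4)], pos=i)
             for i in range(300)]
    _, counts = partition_variants(sites)
    assert sum(counts.values()) == 300


def test_planted_categories_recovered_exactly(small_sim):
    """End-to-end: unfiltered partition equals the generator's truth."""
    sites = [
        VariantSite(contig=r["contig"], pos=r["pos"], ref=r["ref"], alt=r["alt"],
                    gt={"LINE_S": tuple(r["gt_S"]), "LINE_L": tuple(r["gt_L"])},
                    dp={"LINE_S": r["dp_S"], "LINE_L": r["dp_L"]})
        for r in small_sim["records"]
    ]
    sites, counts = partition_variants(sites)
    for s, r in zip(sites, small_sim["records"]):
        assert s.category == r["category"]
    assert sum(counts.values()) == len(sites)


def test_density_table_and_x_zero_fixed(small_sim):
    truth = small_sim["truth"]
    sites, _ = partition_variants([
        VariantSite(contig=r["contig"], pos=r["pos"], ref=r["ref"], alt=r["alt"],
                    gt={"LINE_S": tuple(r["gt_S"]), "LINE_L": tuple(r["gt_L"])},
                    dp={"LINE_S": r["dp_S"], "LINE_L": r["dp_L"]})
        for r in small_sim["records"]
    ])
    classes = {c: v for c, v in truth.contig_classes.items() if c != "Y_L"}
    class_len: dict[str, int] = {}
    for c, v in classes.items():
        class_len[v] = class_len.get(v, 0) + truth.contig_lengths[c]
    dt = density_table(sites, classes, class_len)
    assert dt.count("X", "FIXED_SNV") == 0
    assert dt.count("A", "FIXED_SNV") == 0
    assert dt.count("Y", "FIXED_SNV") > 0
    total = dt.table["n_shared_snp"].sum() + dt.table["n_fixed_snv"].sum()
    expected = sum(s.category in ("SHARED_SNP", "FIXED_SNV") for s in sites)
    assert total == expected
    enr = density_enrichment(dt, ("A", "X"), "SHARED_SNP")
    assert enr.ci_low > 1.0  # autosomes denser in shared SNPs by construction


def test_identical_densities_ci_contains_one():
    sites = [_site(contig="c1", pos=i) for i in range(10)]
    sites += [_site(contig="c2", pos=i) for i in range(10)]
    sites, _ = partition_variants(sites)
    dt = density_table(sites, {"c1": "A", "c2": "X"}, {"A": 10**6, "X": 10**6})
    r = density_enrichment(dt, ("A", "X"), "SHARED_SNP")
    assert r.ci_low < 1.0 < r.ci_high


# --- cis proximity -----------------------------------------------------------


def _gene(gid="g1", contig="Y", start=10_000, end=12_000, strand="+"):
    return GeneModel(gene_id=gid, transcript_id=f"{gid}.t1", contig=contig,
                     start=start, end=end, strand=strand,
                     exons=[(start, end)])


def _fixed(pos, contig="Y"):
    s = _site(contig=contig, pos=pos, gt1=(0, 0), gt2=(1, 1))
    s.category = "FIXED_SNV"
    return s


def test_boundary_exactly_2kb_upstream_is_flagged():
    g = _gene()
    flagged, labels = annotate_cis_proximity([_fixed(8_000)], [g])
    assert flagged == {"g1"}
    assert labels.loc[0, "label"] == "upstream"
    # one bp further is out
    flagged, labels = annotate_cis_proximity([_fixed(7_999)], [g])
    assert flagged == set()
    assert labels.loc[0, "label"] == "intergenic"


def test_downstream_boundary_and_strand_labels():
    g = _gene(strand="-")
    flagged, labels = annotate_cis_proximity([_fixed(13_999)], [g])
    assert flagged == {"g1"}
    # 3' side of the genome, but the gene is on -, so it's upstream
    assert labels.loc[0, "label"] == "upstream"


def test_many_snvs_one_gene_counted_once():
    g = _gene()
    snvs = [_fixed(10_100 + i) for i in range(10)]
    flagged, labels = annotate_cis_proximity(snvs, [g])
    assert flagged == {"g1"}
    assert (labels["label"] == "genic").all()


def test_enlarging_flank_never_unflags():
    rng = np.random.default_rng(22)
    genes = [_gene(f"g{i}", start=s, end=s + 1_000)
             for i, s in enumerate(rng.integers(0, 80_000, 12))]
    snvs = [_fixed(int(p)) for p in rng.integers(0, 90_000, 40)]
    prev: set = set()
    for flank in (0, 500, 2_000, 5_000):
        flagged, _ = annotate_cis_proximity(snvs, genes, flank=flank)
        assert prev <= flagged
        prev = flagged


def test_unknown_contig_warns_and_counts_intergenic():
    with pytest.warns(UserWarning, match="absent from the annotation"):
        flagged, labels = annotate_cis_proximity([_fixed(5, contig="nowhere")], [_gene()])
    assert flagged == set()
    assert labels.loc[0, "label"] == "intergenic"


def test_planted_fixed_snvs_flag_expected_genes(small_sim):
    """Genes flagged == genes whose ±2 kb window holds >=1 planted fixed SNV."""
    truth = small_sim["truth"]
    genes = [g for g in small_sim["annotation"] if g.contig == "Y_S"]
    fixed = [_fixed(r["pos"], contig="Y_S") for r in small_sim["records"]
             if r["category"] == "FIXED_SNV"]
    flagged, _ = annotate_cis_proximity(fixed, genes,
                                        contig_lengths=truth.contig_lengths)
    expected = {
        g.gene_id for g in genes
        if any(g.start - 2_000 <= s.pos < g.end + 2_000 for s in fixed)
    }
    assert flagged == expected
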