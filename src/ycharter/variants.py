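"""Partitioning two-line variant calls into shared SNPs and fixed SNVs.

Two introgression lines sharing an inbred background differ, by
construction, only on the non-recombining Y: a site that is polymorphic in
*both* lines (a shared SNP) reflects the common background, while a site at
which the lines are homozygous for *different* alleles (a fixed SNV) is a
haplotype difference and should appear only on Y-linked contigs.  Sites are
depth-filtered first (default [5, 65], bounds inclusive), counted per
chromosome class into a density table, compared between classes with the
exact odds-ratio machinery, and fixed SNVs are attributed to genes within a
±2 kb cis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .exact_stats import EnrichmentResult, TwoByTwo, fisher_exact
from .models import GeneModel, VariantSite

__all__ = [
    "filter_sites",
    "partition_variants",
    "density_table",
    "density_enrichment",
    "annotate_cis_proximity",
    "DensityTable",
]

CATEGORIES = ("SHARED_SNP", "FIXED_SNV", "OTHER")
_NUCS = set("ACGT")


def filter_sites(
    sites: list[VariantSite],
    min_depth: int = 5,
    max_depth: int = 65,
) -> tuple[list[VariantSite], dict[str, int]]:
    """Keep biallelic SNVs whose depth in every line is inside the window.

    Bounds are inclusive.  Sites with a missing DP in any line are dropped
    and counted under ``no_depth``.  Returns (retained, dropped-by-reason).
    """
    retained: list[VariantSite] = []
    dropped = {"not_snv": 0, "no_depth": 0, "depth_out_of_range": 0}
    for s in sites:
        if len(s.ref) != 1 or len(s.alt) != 1 or s.ref not in _NUCS or s.alt not in _NUCS:
            dropped["not_snv"] += 1
            s.category = "FILTERED"
            continue
        depths = list(s.dp.values())
        if any(d is None for d in depths):
            dropped["no_depth"] += 1
            s.category = "FILTERED"
            continue
        if any(d < min_depth or d > max_depth for d in depths):
            dropped["depth_out_of_range"] += 1
            s.category = "FILTERED"
            continue
        retained.append(s)
    return retained, dropped


def _alleles(gt: tuple[int, int] | None) -> set[int]:
    return set(gt) if gt is not None else set()


def partition_variants(
    sites: list[VariantSite],
    shared_semantics: str = "het_in_both",
) -> tuple[list[VariantSite], dict[str, int]]:
    """Categorize retained sites as SHARED_SNP / FIXED_SNV / OTHER.

    FIXED_SNV: both lines homozygous, for different alleles.  SHARED_SNP:
    the same polymorphism observed in both lines — by default both lines
    heterozygous (``het_in_both``); ``allele_in_both`` relaxes this to both
    alleles of the site being observed across each line's genotype.
    Everything else (missing genotype, polymorphism in one line only) is
    OTHER.  Sites must carry exactly two line samples.
    """
    if shared_semantics not in ("het_in_both", "allele_in_both"):
        raise ValueError(f"unknown shared_semantics {shared_semantics!r}")
    counts = {c: 0 for c in CATEGORIES}
    for s in sites:
        if len(s.gt) != 2:
            raise ValueError(
                f"{s.contig}:{s.pos + 1}: expected exactly two line samples, "
                f"got {len(s.gt)}; select the two lines to compare"
            )
        g1, g2 = (s.gt[k] for k in sorted(s.gt))
        a1, a2 = _alleles(g1), _alleles(g2)
        if not a1 or not a2:
            cat = "OTHER"
        elif len(a1) == 1 and len(a2) == 1 and a1 != a2:
            cat = "FIXED_SNV"
        elif shared_semantics == "het_in_both" and len(a1) == 2 and len(a2) == 2:
            cat = "SHARED_SNP"
        elif shared_semantics == "allele_in_both" and len(a1 | a2) == 2 and a1 == a2:
            cat = "SHARED_SNP"
        else:
            cat = "OTHER"
        s.category = cat
        counts[cat] += 1
    return sites, counts


@dataclass
class DensityTable:
    """Counts and per-bp densities of each variant kind per chromosome class."""

    table: pd.DataFrame  # index: class; columns n_shared_snp, n_fixed_snv, length_bp, ...

    def count(self, chrom_class: str, kind: str) -> int:
        col = "n_shared_snp" if kind == "SHARED_SNP" else "n_fixed_snv"
        return int(self.table.loc[chrom_class, col])

    def length(self, chrom_class: str) -> int:
        return int(self.table.loc[chrom_class, "length_bp"])


def density_table(
    sites: list[VariantSite],
    contig_classes: dict[str, str],
    class_lengths: dict[str, int],
) -> DensityTable:
    """Per-class counts of categorized sites, mirroring a per-chromosome-type
    variant summary.

    ``class_lengths`` supplies the assembled bp per class (the caller
    chooses which length column of its assembly report to use).
    """
    classes = sorted(set(contig_classes.values()) | set(class_lengths))
    rows = {c: {"n_shared_snp": 0, "n_fixed_snv": 0} for c in classes}
    for s in sites:
        cls = contig_classes.get(s.contig)
        if cls is None:
            raise ValueError(f"contig {s.contig} has no class label")
        if s.category == "SHARED_SNP":
            rows[cls]["n_shared_snp"] += 1
        elif s.category == "FIXED_SNV":
            rows[cls]["n_fixed_snv"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["length_bp"] = pd.Series(class_lengths).reindex(df.index).fillna(0).astype("int64")
    df["shared_snp_per_bp"] = df["n_shared_snp"] / df["length_bp"].where(df["length_bp"] > 0)
    df["fixed_snv_per_bp"] = df["n_fixed_snv"] / df["length_bp"].where(df["length_bp"] > 0)
    df.index.name = "chrom_class"
    return DensityTable(df)


def density_enrichment(
    dtable: DensityTable,
    class_pair: tuple[str, str],
    variant_kind: str,
    conf_level: float = 0.95,
) -> EnrichmentResult:
    """Exact odds-ratio test of count-per-bp between two chromosome classes.

    The first class of the pair is the focal row, so an odds ratio above 1
    means that class is denser.
    """
    c1, c2 = class_pair
    n1, n2 = dtable.count(c1, variant_kind), dtable.count(c2, variant_kind)
    l1, l2 = dtable.length(c1), dtable.length(c2)
    if l1 <= 0 or l2 <= 0:
        raise ValueError(f"both classes need positive length, got {l1} and {l2}")
    return fisher_exact(TwoByTwo(n1, l1 - n1, n2, l2 - n2), conf_level=conf_level)


def annotate_cis_proximity(
    fixed_sites: list[VariantSite],
    genes: list[GeneModel],
    flank: int = 2_000,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Attribute fixed SNVs to genes within a ±``flank`` cis window.

    A gene is flagged when at least one fixed SNV lies in
    [gene_start - flank, gene_end + flank] (inclusive window, clipped to the
    contig); each gene is counted once regardless of how many SNVs hit it.
    Each SNV is additionally labeled genic / upstream / downstream /
    intergenic relative to the nearest flagged gene's strand (the flagging
    itself is strand-agnostic: regulatory regions sit on both sides).
    Returns (flagged gene ids, per-SNV label table).
    """
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    flagged: set[str] = set()
    rows = []
    warned: set[str] = set()
    for s in fixed_sites:
        contig_genes = by_contig.get(s.contig)
        label = "intergenic"
        if contig_genes is None:
            if s.contig not in warned:
                warnings.warn(
                    f"contig {s.contig} absent from the annotation; "
                    f"its fixed SNVs are counted intergenic",
                    stacklevel=2,
                )
                warned.add(s.contig)
        else:
            clen = (contig_lengths or {}).get(s.contig)
            best = None  # (genic?, distance, label) — nearest gene names the label
            for g in contig_genes:
                lo = max(0, g.start - flank)
                hi = g.end + flank
                if clen is not None:
                    hi = min(hi, clen)
                # pos is 0-based, so [lo, hi) includes positions exactly
                # `flank` bp beyond either gene end
                if not (lo <= s.pos < hi):
                    continue
                flagged.add(g.gene_id)
                if g.start <= s.pos < g.end:
                    cand = (0, 0, "genic")
                elif s.pos < g.start:
                    cand = (1, g.start - s.pos,
                            "upstream" if g.strand == "+" else "downstream")
                else:
                    cand = (1, s.pos - g.end + 1,
                            "downstream" if g.strand == "+" else "upstream")
                if best is None or cand[:2] < best[:2]:
                    best = cand
            if best is not None:
                label = best[2]
        rows.append(dict(contig=s.contig, pos=s.pos, label=label))
    return flagged, pd.DataFrame(rows, columns=["contig", "pos", "label"])
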