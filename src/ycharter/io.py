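"""Readers and writers for the standard formats the pipeline touches.

All readers return records in the package's internal 0-based half-open
coordinates; writers convert back, so read-write-read round trips are
identical.  FASTA goes through Biopython, VCF through pysam, GFF3 and the
simpler tabular formats through thin converters with explicit coordinate
handling.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, HomologyHit, VariantSite

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences by id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            cols = [g.contig, "ycharter", "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(cols + [f"ID={g.gene_id}"]) + "\n")
            fh.write(
                "\t".join(
                    [g.contig, "ycharter", "mRNA", str(g.start + 1), str(g.end), ".", g.strand, ".",
                     f"ID={g.transcript_id};Parent={g.gene_id}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        "\t".join(
                            [g.contig, "ycharter", ftype, str(s + 1), str(e), ".", g.strand,
                             "0" if ftype == "CDS" else ".",
                             f"ID={g.transcript_id}.{ftype}{i};Parent={g.transcript_id}"]
                        )
                        + "\n"
                    )


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into :class:`GeneModel` records.

    Malformed lines raise with their line number; a feature with
    ``end < start`` is rejected.
    """
    genes: dict[str, dict] = {}
    tx2gene: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _, ftype, start, end, _, strand, _, attrs = cols
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if e1 < s1:
                raise ValueError(f"{path}:{lineno}: end < start")
            a = _parse_attrs(attrs)
            s, e = s1 - 1, e1  # to 0-based half-open
            if ftype == "gene":
                genes[a["ID"]] = dict(contig=contig, start=s, end=e, strand=strand)
            elif ftype == "mRNA":
                tx2gene[a["ID"]] = a.get("Parent", a["ID"])
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((s, e))
    out = []
    for tx, gene_id in tx2gene.items():
        g = genes[gene_id]
        out.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tx,
                contig=g["contig"],
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                exons=sorted(exons.get(tx, [])),
            )
        )
    out.sort(key=lambda g: (g.contig, g.start))
    return out


# ---------------------------------------------------------------------------
# VCF (two-line variant calls)


def write_vcf(
    sites: list[VariantSite],
    contig_lengths: dict[str, int],
    samples: list[str],
    path: str | Path,
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "ycharter")
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"), ("Description", "Read depth")]
    )
    for s in samples:
        header.add_sample(s)
    order = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for site in sorted(sites, key=lambda v: (order.get(v.contig, 1 << 30), v.pos)):
            rec = vf.new_record(
                contig=site.contig, start=site.pos, stop=site.pos + 1,
                alleles=(site.ref, site.alt),
            )
            for s in samples:
                rec.samples[s]["GT"] = site.gt.get(s)
                dp = site.dp.get(s)
                if dp is not None:
                    rec.samples[s]["DP"] = dp
            vf.write(rec)


def read_vcf(path: str | Path) -> tuple[list[VariantSite], list[str], dict[str, int]]:
    """Returns (sites, samples, header contig lengths)."""
    import pysam

    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        header_contigs = {name: c.length for name, c in vf.header.contigs.items()}
        for rec in vf:
            alts = rec.alts or ()
            alt = alts[0] if alts else "."
            gt = {}
            dp = {}
            for s in samples:
                call = rec.samples[s]
                g = call.get("GT")
                gt[s] = tuple(g) if g is not None and None not in g else None
                dp[s] = call.get("DP")
            sites.append(
                VariantSite(
                    contig=rec.contig, pos=rec.start, ref=rec.ref, alt=alt, gt=gt, dp=dp,
                )
            )
    return sites, samples, header_contigs


# ---------------------------------------------------------------------------
# coverage TSV, BED, BLAST tabular


def write_coverage_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "sample", "sex", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED is already 0-based half-open; kept as-is."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name"], usecols=range(4),
    )
    if (df["end"] < df["start"]).any():
        bad = df.index[df["end"] < df["start"]][0]
        raise ValueError(f"{path}: interval with end < start at data line {bad + 1}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_outfmt6(
    path: str | Path,
    query_lengths: dict[str, int],
    subject_classes: dict[str, str] | None = None,
) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output.

    Query coverage is not a column of outfmt 6; it is computed from the
    qstart/qend span and a side table of query lengths.  Subject contig
    classes, when supplied, map each subject id to A/X/Y/SHORT.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_OUTFMT6_COLS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        if row.qseqid == row.sseqid:
            continue
        if row.qseqid not in query_lengths:
            raise ValueError(f"no query length supplied for {row.qseqid}")
        span = abs(int(row.qend) - int(row.qstart)) + 1  # outfmt6 is 1-based inclusive
        hits.append(
            HomologyHit(
                query=row.qseqid,
                subject=row.sseqid,
                percent_identity=float(row.pident),
                query_coverage=span / query_lengths[row.qseqid],
                bit_score=float(row.bitscore),
                evalue=float(row.evalue),
                subject_class=(subject_classes or {}).get(row.sseqid),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# JSON + newick


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as newick."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
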