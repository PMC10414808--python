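"""Ground-truthed synthetic XY genomes for offline pipeline testing.

The generator emulates a study design in which two Y-haplotype introgression
lines (S and L) share an inbred autosomal and X background and differ only
on the non-recombining Y: the assembly carries autosomal contigs, one X
contig, one Y contig per haplotype and a few sub-100 kb contigs; male
samples see half-depth X and haploid Y coverage while females see no Y
coverage beyond a mismapping floor; the Y carries gene families at >99.9%
nucleotide identity (amplicons), genes copied from the X (gametologs) and
from autosomes (paralogs) at configurable protein identity, and tandem
copies of a truncated candidate growth gene whose copy number differs
between the haplotypes (the 5'-most exons missing, the next exon partial).

Background sequence is i.i.d. uniform nucleotides: repeat structure is out
of scope and the identity thresholds of the downstream classifiers are what
matter.  Every planted entity is recorded in a :class:`SimulationTruth` so
downstream calls can be scored exactly.  The same seed and config produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import revcomp
from .models import GeneModel

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "simulate_coverage",
    "simulate_line_variants",
    "simulate_candidate_genealogy",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the 61 sense codons of the standard code
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_CODON_TABLE = {}
for _c in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq

    _CODON_TABLE[_c] = str(_Seq(_c).translate())


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic design.

    Variant densities default to the per-bp rates observed between two real
    Y introgression lines (shared SNPs ~2.4e-3/bp on autosomes, ~8.2e-5/bp
    on the X; fixed differences ~2.6e-4/bp on the Y and none on the X),
    scaled onto desk-sized contigs.  Sample sizes default to the 4 male +
    4 female resequencing design.
    """

    # genome geometry (bp)
    n_autosomes: int = 6
    autosome_len: int = 250_000
    x_len: int = 150_000
    y_len: int = 150_000          # Y core; candidate block is appended
    n_short_contigs: int = 2
    short_len: int = 50_000
    # samples and depth
    n_male_samples: int = 4
    n_female_samples: int = 4
    mean_depth: float = 30.0
    depth_dispersion: float = 0.02  # CV^2 of per-contig mean depth; 0 = exact
    mismap_epsilon: float = 0.01    # female Y depth floor, fraction of mean
    # variant densities (per bp)
    shared_snp_rate_A: float = 2.43e-3
    shared_snp_rate_X: float = 8.2e-5
    shared_snp_rate_Y: float = 2.1e-5
    fixed_snv_rate_Y: float = 2.6e-4
    private_snp_rate: float = 2.0e-5   # one-line-only het sites (category OTHER)
    depth_outlier_fraction: float = 0.05  # per-site depths planted outside [5, 65]
    # gene catalogue
    n_gametologs: int = 8
    n_paralogs: int = 10
    n_both: int = 4
    n_y_novel: int = 3
    n_short_homologs: int = 1     # Y genes with an extra copy on a <100 kb contig
    gene_len: int = 1_500         # CDS length of ordinary genes (multiple of 3)
    gametolog_identity: float = 0.90   # protein identity of the X copy
    paralog_identity: float = 0.88     # protein identity of the autosomal copy
    # ampliconic families
    n_amplicon_families: int = 5
    copies_per_family: tuple[int, int] = (2, 4)
    amplicon_identity: float = 0.9995  # nucleotide, must stay > 0.999
    # candidate gene (full copy on an autosome, truncated tandem copies on Y)
    candidate_copies_hapS: int = 3
    candidate_copies_hapL: int = 1
    candidate_exons: int = 25
    truncated_exons: int = 5      # plus one partial exon after them
    candidate_exon_len: int = 180
    candidate_intron_len: int = 300
    candidate_spacer: int = 2_000
    candidate_exon_divergence: float = 0.01    # Y copy exons vs autosomal
    candidate_intron_divergence: float = 0.08  # Y copy introns vs autosomal
    candidate_copy_divergence: float = 0.002   # between Y copies
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "shared_snp_rate_A": self.shared_snp_rate_A,
            "shared_snp_rate_X": self.shared_snp_rate_X,
            "shared_snp_rate_Y": self.shared_snp_rate_Y,
            "fixed_snv_rate_Y": self.fixed_snv_rate_Y,
            "private_snp_rate": self.private_snp_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 0.05:
                raise ValueError(f"{name} must be in [0, 0.05], got {r}")
        for name in ("autosome_len", "x_len", "y_len", "short_len", "gene_len",
                     "candidate_exon_len", "candidate_intron_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.999 < self.amplicon_identity <= 1.0:
            raise ValueError("amplicon_identity must be in (0.999, 1]")
        for name in ("gametolog_identity", "paralog_identity"):
            v = getattr(self, name)
            if not 0.80 < v < 1.0:
                raise ValueError(f"{name} must be in (0.80, 1)")
        if self.gene_len % 3:
            raise ValueError("gene_len must be a multiple of 3")
        if self.candidate_exon_len % 2:
            raise ValueError("candidate_exon_len must be even (partial exon is its 3' half)")
        if self.truncated_exons + 1 >= self.candidate_exons:
            raise ValueError("truncated_exons + 1 must be < candidate_exons")
        if min(self.candidate_copies_hapS, self.candidate_copies_hapL) < 0:
            raise ValueError("candidate copy counts must be >= 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


@dataclass
class SimulationTruth:
    """Everything the generator planted, for exact downstream scoring."""

    contig_classes: dict[str, str]
    contig_lengths: dict[str, int]
    gene_origins: dict[str, str]          # transcript id -> planted origin category
    amplicon_families: dict[str, list[str]]
    candidate_copies: dict[str, list[dict]]   # haplotype -> [{start, end, exon_status}]
    variants: list[dict] = field(default_factory=list)
    samples: dict[str, str] = field(default_factory=dict)  # sample -> sex

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _str_to_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


def _random_cds(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=length // 3)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _mutate_nt(seq: str, rate_or_count, rng: np.random.Generator) -> str:
    """Substitute bases at distinct positions; never introduces indels."""
    arr = _str_to_arr(seq)
    n = len(arr)
    k = int(round(rate_or_count * n)) if isinstance(rate_or_count, float) else int(rate_or_count)
    k = min(k, n)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return _arr_to_str(arr)


def _mutate_codons(cds: str, target_identity: float, rng: np.random.Generator) -> str:
    """Replace codons so the protein identity equals ``target_identity``.

    Each selected codon is swapped for a random sense codon encoding a
    different amino acid, so protein identity is exact while nucleotide
    identity stays >= the protein identity.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    k = int(round((1.0 - target_identity) * n))
    pos = rng.choice(n, size=k, replace=False)
    for p in pos:
        old_aa = _CODON_TABLE[codons[p]]
        while True:
            new = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
            if _CODON_TABLE[new] != old_aa:
                codons[p] = new
                break
    return "".join(codons)


def _layout(
    rng: np.random.Generator,
    contig_len: int,
    items: list[tuple[str, str]],
    pad: int = 1_000,
    spacer: tuple[int, int] = (500, 1_500),
) -> list[tuple[str, int, int]]:
    """Place sequences left to right with random intergenic spacers."""
    pos = pad
    placed = []
    for name, seq in items:
        pos += int(rng.integers(spacer[0], spacer[1] + 1))
        end = pos + len(seq)
        if end > contig_len - pad:
            raise ValueError(
                f"planted content does not fit: {name} would end at {end} "
                f"on a {contig_len} bp contig"
            )
        placed.append((name, pos, end))
        pos = end
    return placed


def _paste(arr: np.ndarray, placements: list[tuple[str, int, int]], seqs: dict[str, str]) -> None:
    for name, s, e in placements:
        arr[s:e] = _str_to_arr(seqs[name])


# ---------------------------------------------------------------------------
# candidate gene construction


def _candidate_full(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, list[tuple[int, int]]]:
    """The complete candidate gene: exon/intron sequence and exon intervals."""
    exon_seqs = [_random_cds(rng, cfg.candidate_exon_len) for _ in range(cfg.candidate_exons)]
    introns = [
        _arr_to_str(_random_seq_arr(rng, cfg.candidate_intron_len))
        for _ in range(cfg.candidate_exons - 1)
    ]
    parts = []
    exons = []
    pos = 0
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        exons.append((pos, pos + len(ex)))
        pos += len(ex)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    return "".join(parts), exons


def _truncate_candidate(
    gene_seq: str, exons: list[tuple[int, int]], cfg: SimulationConfig
) -> tuple[str, list[tuple[int, int]], list[str]]:
    """Drop the first ``truncated_exons`` exons and halve the next one.

    The partial exon keeps its 3' half (the breakpoint is not observed in
    real data; the midpoint is this generator's convention).  Returns the
    truncated sequence, its exon intervals, and the per-exon status of the
    *original* exon numbering.
    """
    t = cfg.truncated_exons
    partial_s, partial_e = exons[t]
    half = partial_s + (partial_e - partial_s) // 2
    keep_from = half
    seq = gene_seq[keep_from:]
    new_exons = [(half - keep_from, partial_e - keep_from)]
    for s, e in exons[t + 1 :]:
        new_exons.append((s - keep_from, e - keep_from))
    status = (
        ["absent"] * t + ["partial"] + ["present"] * (cfg.candidate_exons - t - 1)
    )
    return seq, new_exons, status


def _diverge_candidate_copy(
    seq: str, exons: list[tuple[int, int]], rate_exon: float, rate_intron: float,
    rng: np.random.Generator,
) -> str:
    """Mutate exonic and intronic positions of a gene region at separate rates."""
    arr = _str_to_arr(seq)
    mask = np.zeros(len(arr), dtype=bool)
    for s, e in exons:
        mask[s:e] = True
    for region_mask, rate in ((mask, rate_exon), (~mask, rate_intron)):
        idx = np.flatnonzero(region_mask)
        k = int(round(rate * len(idx)))
        if k:
            for p in rng.choice(idx, size=k, replace=False):
                choices = _BASES[_BASES != arr[p]]
                arr[p] = rng.choice(choices)
    return _arr_to_str(arr)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SimulationTruth]:
    """Generate the assembly, its gene annotation, and the planted truth.

    Returns ``(assembly, annotation, truth)`` where the assembly maps contig
    id to sequence (autosomes ``A1..``, ``X1``, the two Y haplotype contigs
    ``Y_S``/``Y_L``, short contigs ``SHORT1..``), the annotation covers the
    reference (S) contigs, and the truth records classes, planted origins,
    families, candidate copies and the fixed differences applied to Y_L.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cfg = config

    # --- gene catalogue -----------------------------------------------------
    y_items: list[tuple[str, str]] = []
    origins: dict[str, str] = {}
    x_copies: dict[str, str] = {}
    a_copies: dict[str, str] = {}
    short_copies: dict[str, str] = {}
    families: dict[str, list[str]] = {}

    def add(tid: str, cds: str, origin: str) -> None:
        y_items.append((tid, cds))
        origins[tid] = origin

    for i in range(cfg.n_gametologs):
        tid = f"GAM{i+1}.t1"
        cds = _random_cds(rng, cfg.gene_len)
        add(tid, cds, "EXCLUSIVE_X")
        x_copies[f"X_{tid}"] = _mutate_codons(cds, cfg.gametolog_identity, rng)
    for i in range(cfg.n_paralogs):
        tid = f"PAR{i+1}.t1"
        cds = _random_cds(rng, cfg.gene_len)
        add(tid, cds, "EXCLUSIVE_A")
        a_copies[f"A_{tid}"] = _mutate_codons(cds, cfg.paralog_identity, rng)
    for i in range(cfg.n_both):
        tid = f"BOTH{i+1}.t1"
        cds = _random_cds(rng, cfg.gene_len)
        add(tid, cds, "BOTH")
        x_copies[f"X_{tid}"] = _mutate_codons(cds, cfg.gametolog_identity, rng)
        a_copies[f"A_{tid}"] = _mutate_codons(cds, cfg.paralog_identity, rng)
    for i in range(cfg.n_y_novel):
        add(f"NOV{i+1}.t1", _random_cds(rng, cfg.gene_len), "NO_HOMOLOG")
    for i in range(cfg.n_short_homologs):
        tid = f"UNC{i+1}.t1"
        cds = _random_cds(rng, cfg.gene_len)
        add(tid, cds, "EXCLUDED_UNCATEGORIZED")
        x_copies[f"X_{tid}"] = _mutate_codons(cds, cfg.gametolog_identity, rng)
        short_copies[f"S_{tid}"] = _mutate_codons(cds, cfg.gametolog_identity, rng)
    for f in range(cfg.n_amplicon_families):
        fam_id = f"AMPF{f+1}"
        n_copies = int(rng.integers(cfg.copies_per_family[0], cfg.copies_per_family[1] + 1))
        base = _random_cds(rng, cfg.gene_len)
        members = []
        for j in range(n_copies):
            tid = f"{fam_id}_c{j+1}.t1"
            seq = base if j == 0 else _mutate_nt(base, 1.0 - cfg.amplicon_identity, rng)
            add(tid, seq, "NO_HOMOLOG")
            members.append(tid)
        families[fam_id] = members

    # --- candidate gene -----------------------------------------------------
    cand_seq, cand_exons = _candidate_full(rng, cfg)
    trunc_seq, trunc_exons, exon_status = _truncate_candidate(cand_seq, cand_exons, cfg)

    def candidate_block(n_copies: int, rng_block: np.random.Generator):
        """Tandem truncated copies separated by random spacers."""
        parts, copies, pos = [], [], 0
        for j in range(n_copies):
            copy_seq = _diverge_candidate_copy(
                trunc_seq, trunc_exons,
                cfg.candidate_exon_divergence + j * cfg.candidate_copy_divergence,
                cfg.candidate_intron_divergence + j * cfg.candidate_copy_divergence,
                rng_block,
            )
            copies.append(dict(start=pos, end=pos + len(copy_seq),
                               exons=[(pos + s, pos + e) for s, e in trunc_exons],
                               exon_status=list(exon_status)))
            parts.append(copy_seq)
            pos += len(copy_seq)
            spacer = _arr_to_str(_random_seq_arr(rng_block, cfg.candidate_spacer))
            parts.append(spacer)
            pos += len(spacer)
        return "".join(parts), copies

    # --- assemble contigs ---------------------------------------------------
    assembly: dict[str, str] = {}
    annotation: list[GeneModel] = []
    contig_classes: dict[str, str] = {}

    def build_contig(name, length, items, copies_seqs, chrom_class):
        arr = _random_seq_arr(rng, length)
        placements = _layout(rng, length, items)
        _paste(arr, placements, copies_seqs)
        assembly[name] = _arr_to_str(arr)
        contig_classes[name] = chrom_class
        for tid, s, e in placements:
            gid = tid.rsplit(".", 1)[0]
            annotation.append(
                GeneModel(gene_id=gid, transcript_id=tid, contig=name,
                          start=s, end=e, strand="+", exons=[(s, e)])
            )

    # Y core: all Y genes (candidate block appended afterwards)
    y_seqs = dict(y_items)
    y_arr_items = list(y_items)
    y_core_placements = _layout(rng, cfg.y_len, y_arr_items)
    y_core = _random_seq_arr(rng, cfg.y_len)
    _paste(y_core, y_core_placements, y_seqs)

    block_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    block_S, copies_S = candidate_block(cfg.candidate_copies_hapS, block_rng)
    block_L, copies_L = candidate_block(cfg.candidate_copies_hapL, block_rng)
    tail = _arr_to_str(_random_seq_arr(rng, 2_000))

    if cfg.candidate_copies_hapS and len(trunc_seq) > cfg.y_len:
        raise ValueError(
            f"candidate gene ({len(trunc_seq)} bp truncated) is longer than the "
            f"Y contig core ({cfg.y_len} bp)"
        )

    core_str = _arr_to_str(y_core)
    y_s = core_str + block_S + tail

    # fixed differences: plant on the shared core only, so reference (S)
    # coordinates are valid for both haplotypes
    n_fixed = rng.binomial(cfg.y_len, cfg.fixed_snv_rate_Y)
    fixed_pos = np.sort(rng.choice(cfg.y_len, size=n_fixed, replace=False))
    core_l_arr = _str_to_arr(core_str)
    fixed_records = []
    for p in fixed_pos:
        ref = core_str[p]
        choices = _BASES[_BASES != ord(ref)]
        alt = chr(rng.choice(choices))
        core_l_arr[p] = ord(alt)
        fixed_records.append(
            dict(contig="Y_S", pos=int(p), ref=ref, alt=alt, category="FIXED_SNV")
        )
    y_l = _arr_to_str(core_l_arr) + block_L + tail

    assembly["Y_S"] = y_s
    assembly["Y_L"] = y_l
    contig_classes["Y_S"] = "Y"
    contig_classes["Y_L"] = "Y"
    for tid, s, e in y_core_placements:
        gid = tid.rsplit(".", 1)[0]
        annotation.append(
            GeneModel(gene_id=gid, transcript_id=tid, contig="Y_S",
                      start=s, end=e, strand="+", exons=[(s, e)])
        )
    # candidate Y copies annotated on the reference haplotype
    block_offset = len(core_str)
    truth_copies_S = []
    for j, cp in enumerate(copies_S):
        tid = f"CANDY{j+1}.t1"
        exons = [(block_offset + s, block_offset + e) for s, e in cp["exons"]]
        annotation.append(
            GeneModel(gene_id=f"CANDY{j+1}", transcript_id=tid, contig="Y_S",
                      start=exons[0][0], end=exons[-1][1], strand="+", exons=exons)
        )
        origins[tid] = "EXCLUSIVE_A"
        truth_copies_S.append(
            dict(start=block_offset + cp["start"], end=block_offset + cp["end"],
                 exon_status=cp["exon_status"])
        )
    off_l = len(core_str)
    truth_copies_L = [
        dict(start=off_l + cp["start"], end=off_l + cp["end"], exon_status=cp["exon_status"])
        for cp in copies_L
    ]

    # autosomes: paralog copies spread round-robin, candidate full gene on A1
    a_names = [f"A{i+1}" for i in range(cfg.n_autosomes)]
    per_contig: dict[str, list[tuple[str, str]]] = {n: [] for n in a_names}
    for i, (name, seq) in enumerate(sorted(a_copies.items())):
        per_contig[a_names[i % len(a_names)]].append((name, seq))
    per_contig[a_names[0]].insert(0, ("CAND_A.t1", cand_seq))
    for name in a_names:
        arr = _random_seq_arr(rng, cfg.autosome_len)
        placements = _layout(rng, cfg.autosome_len, per_contig[name])
        seqs = dict(per_contig[name])
        _paste(arr, placements, seqs)
        assembly[name] = _arr_to_str(arr)
        contig_classes[name] = "A"
        for tid, s, e in placements:
            if tid == "CAND_A.t1":
                exons = [(s + es, s + ee) for es, ee in cand_exons]
                annotation.append(
                    GeneModel(gene_id="CAND_A", transcript_id=tid, contig=name,
                              start=s, end=e, strand="+", exons=exons)
                )
            else:
                annotation.append(
                    GeneModel(gene_id=tid.rsplit(".", 1)[0], transcript_id=tid,
                              contig=name, start=s, end=e, strand="+", exons=[(s, e)])
                )

    # X contig
    build_contig("X1", cfg.x_len, sorted(x_copies.items()), x_copies, "X")
    # short contigs
    short_items: dict[str, list[tuple[str, str]]] = {
        f"SHORT{i+1}": [] for i in range(cfg.n_short_contigs)
    }
    for i, (name, seq) in enumerate(sorted(short_copies.items())):
        short_items[f"SHORT{(i % cfg.n_short_contigs) + 1}"].append((name, seq))
    for name, items in short_items.items():
        build_contig(name, cfg.short_len, items, dict(items), "SHORT")

    truth = SimulationTruth(
        contig_classes=contig_classes,
        contig_lengths={k: len(v) for k, v in assembly.items()},
        gene_origins=origins,
        amplicon_families=families,
        candidate_copies={"S": truth_copies_S, "L": truth_copies_L},
        variants=fixed_records,
    )
    annotation.sort(key=lambda g: (g.contig, g.start))
    return assembly, annotation, truth


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-contig per-sample mean depth, tidy table.

    The mean depth of a sample over a contig is drawn from a Gamma
    distribution with mean ``mean_depth * ploidy_factor`` and squared
    coefficient of variation ``depth_dispersion`` (the mixing distribution
    of a negative-binomial read count, appropriate for a depth averaged over
    a long contig).  Dispersion 0 gives the exact expected depth.  Ploidy
    factors: autosomes and short contigs 1 in both sexes; X 0.5 in males;
    Y 0.5 in males and ``mismap_epsilon`` in females.
    """
    cfg = config
    if cfg.n_male_samples == 0 or cfg.n_female_samples == 0:
        raise ValueError("need at least one sample of each sex for a coverage comparison")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples = [(f"M{i+1}", "male") for i in range(cfg.n_male_samples)] + [
        (f"F{i+1}", "female") for i in range(cfg.n_female_samples)
    ]
    factors = {
        "A": {"male": 1.0, "female": 1.0},
        "SHORT": {"male": 1.0, "female": 1.0},
        "X": {"male": 0.5, "female": 1.0},
        "Y": {"male": 0.5, "female": cfg.mismap_epsilon},
    }
    rows = []
    for contig, cls in truth.contig_classes.items():
        for sample, sex in samples:
            mu = cfg.mean_depth * factors[cls][sex]
            if cfg.depth_dispersion == 0 or mu == 0:
                depth = mu
            else:
                shape = 1.0 / cfg.depth_dispersion
                depth = float(rng.gamma(shape, mu / shape))
            rows.append((contig, sample, sex, depth))
    truth.samples = {s: sex for s, sex in samples}
    return pd.DataFrame(rows, columns=["contig", "sample", "sex", "mean_depth"])


# ---------------------------------------------------------------------------
# variants


def _site_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Depth around mean_depth; a configured fraction falls outside [5, 65]."""
    if rng.random() < cfg.depth_outlier_fraction:
        if rng.random() < 0.5:
            return int(rng.integers(0, 5))
        return int(rng.integers(66, 131))
    d = int(rng.poisson(cfg.mean_depth))
    return min(max(d, 5), 65)


def simulate_line_variants(
    truth: SimulationTruth,
    config: SimulationConfig,
    assembly: dict[str, str],
) -> list[dict]:
    """Plant the two-line variant table on reference (S) coordinates.

    Shared SNPs (heterozygous in both lines) go on autosomes and the X at
    their class rates plus a trickle on the Y core; fixed differences (taken
    from the genome truth) are homozygous reference in line S and homozygous
    alternate in line L; line-private heterozygous sites are planted at a
    low rate and are the ground truth for the OTHER category.  Per-site
    depths exercise the [5, 65] depth filter.  Extends and returns
    ``truth.variants``.
    """
    cfg = config
    total_rate = max(
        cfg.shared_snp_rate_A + cfg.private_snp_rate,
        cfg.shared_snp_rate_X + cfg.private_snp_rate,
        cfg.shared_snp_rate_Y + cfg.fixed_snv_rate_Y,
    )
    if total_rate > 1.0:
        raise ValueError("configured rates imply more than one variant per bp")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    records: list[dict] = []
    taken: dict[str, set[int]] = {}
    for rec in truth.variants:  # fixed SNVs planted by simulate_genome
        taken.setdefault(rec["contig"], set()).add(rec["pos"])
        rec = dict(rec)
        rec["gt_S"], rec["gt_L"] = (0, 0), (1, 1)
        rec["dp_S"], rec["dp_L"] = _site_depth(rng, cfg), _site_depth(rng, cfg)
        records.append(rec)

    def plant(contig: str, rate: float, category: str) -> None:
        seq = assembly[contig]
        # shared background only: keep clear of the haplotype-specific block
        span = cfg.y_len if contig == "Y_S" else len(seq)
        n = rng.binomial(span, rate)
        used = taken.setdefault(contig, set())
        positions = []
        while len(positions) < n:
            p = int(rng.integers(0, span))
            if p not in used:
                used.add(p)
                positions.append(p)
        for p in sorted(positions):
            ref = seq[p]
            choices = _BASES[_BASES != ord(ref)]
            alt = chr(rng.choice(choices))
            if category == "SHARED_SNP":
                gts = ((0, 1), (0, 1))
            else:  # OTHER: heterozygous in one line only
                gts = ((0, 1), (0, 0)) if rng.random() < 0.5 else ((0, 0), (0, 1))
            records.append(
                dict(contig=contig, pos=p, ref=ref, alt=alt, category=category,
                     gt_S=gts[0], gt_L=gts[1],
                     dp_S=_site_depth(rng, cfg), dp_L=_site_depth(rng, cfg))
            )

    for contig, cls in truth.contig_classes.items():
        if contig == "Y_L":
            continue  # calls are on reference coordinates
        if cls == "A":
            plant(contig, cfg.shared_snp_rate_A, "SHARED_SNP")
            plant(contig, cfg.private_snp_rate, "OTHER")
        elif cls == "SHORT":
            plant(contig, cfg.shared_snp_rate_A, "SHARED_SNP")
        elif cls == "X":
            plant(contig, cfg.shared_snp_rate_X, "SHARED_SNP")
            plant(contig, cfg.private_snp_rate, "OTHER")
        elif cls == "Y" and contig == "Y_S":
            plant(contig, cfg.shared_snp_rate_Y, "SHARED_SNP")

    records.sort(key=lambda r: (r["contig"], r["pos"]))
    truth.variants = records
    return records


# ---------------------------------------------------------------------------
# candidate genealogy fixture


def simulate_candidate_genealogy(
    seed: int,
    length: int = 3_000,
    n_y_shared: int = 40,
    n_ab_shared: int = 15,
    n_private: int = 4,
) -> dict[str, str]:
    """Exonic sequences mirroring the candidate gene's inferred history.

    The autosomal copies of the two assemblies (``A_S``, ``A_L``) are
    identical; all Y copies share ``n_y_shared`` derived substitutions
    (the translocation predates the haplotype split); ``Y_S_a`` and
    ``Y_S_b`` share ``n_ab_shared`` additional ones; every Y copy carries a
    few private substitutions.  Returns label -> sequence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    anc = _random_cds(rng, length - length % 3)
    n = len(anc)
    pool = rng.permutation(n)
    y_sites = pool[:n_y_shared]
    ab_sites = pool[n_y_shared : n_y_shared + n_ab_shared]
    cursor = n_y_shared + n_ab_shared

    def apply(seq: str, sites: np.ndarray) -> str:
        arr = _str_to_arr(seq)
        for p in sites:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
        return _arr_to_str(arr)

    y_base = apply(anc, y_sites)
    ab_base = apply(y_base, ab_sites)
    out = {"A_S": anc, "A_L": anc}
    for label, base in (("Y_S_a", ab_base), ("Y_S_b", ab_base), ("Y_S_c", y_base), ("Y_L", y_base)):
        sites = pool[cursor : cursor + n_private]
        cursor += n_private
        out[label] = apply(base, sites)
    return out
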