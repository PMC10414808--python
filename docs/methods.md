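# Methods

## Coverage model and sex-linkage calls

Read depth carries the sex-linkage signal through ploidy: autosomes are
diploid in both sexes, the X is hemizygous in males (expected male:female
normalized ratio 0.5:1) and the Y is male-limited (1:0, up to mismapping).
Each sample's depths are divided by that sample's **median over contigs
≥ `min_contig_len`** (default 100 kb), which absorbs library size; the
median is anchored by autosomes as long as they dominate the long-contig
set, which holds in real assemblies and in the generator's defaults.

Sample sexing clusters samples by 2-means on the normalized depths of the
most variable contigs (default: top 5%, at least two). Variance is ranked
and clustered on **log10(depth + 0.01)**: a Y-linked contig's female
dropout spans orders of magnitude, which the log scale turns into the
dominant signal, whereas on the linear scale multiplicative noise from
high-mean autosomes can outrank it. Which cluster is XY is decided by a
per-contig vote rather than by overall mean: on a contig where one group's
mean is ≤0.15 of the other's (Y-like), the depleted group is XX; on a
contig where the lower group sits at 0.3–0.8 of the higher (X-like), the
lower group is XY. The overall-lower-mean rule alone inverts all labels
whenever the most variable contig happens to be Y-linked, where females,
not males, have the lower depth.

Per-contig calls use a Welch (unequal-variance) *t*-test between the sex
groups — the safe default when group variances differ, and the reason each
group needs ≥2 samples. Gates, in order: length < 100 kb → `SHORT` (never
called); p > α (default 0.05, optional Bonferroni) **or** relative
difference |M−F|/max(M,F) < 0.10 → `AUTOSOME` (the conservative filter for
weakly diverged contigs); female mean ≤ 0.1 × male mean → `Y`; M:F ratio in
[0.3, 0.7] → `X`; otherwise `AMBIGUOUS`. The ratio windows are deliberate
artifact choices around the ideal 0.5 and 0 — real coverage deviates from
the strict expectation. In the noiseless limit both group variances are 0
and the t-test degenerates; the caller then reports p = 0 for unequal
means and p = 1 for equal ones rather than NaN.

## Local alignment

Homology search at desk scale uses a seed-and-extend local aligner: exact
k-mer seeds (k = 11 nucleotide / 4 protein) from a hash index of the
subject, clustered by diagonal (band 48) and by subject-position gaps, each
cluster polished with a full affine-gap Smith–Waterman (numba-compiled)
restricted to a window around the seeds. Scoring is the classic default
set: +2/−3 with gap open 5 / extend 2 for nucleotide, BLOSUM62 with 11/1
for protein (a length-L gap costs open + L·extend). Percent identity is
matches / alignment columns (gap columns included); query coverage is the
aligned query span over query length. Bit scores use the Karlin–Altschul
transform with the published gapped parameters for these schemes
(λ = 0.625, K = 0.41 nucleotide; λ = 0.267, K = 0.041 protein); no E-values
are produced internally — when hits carry no E-value the origin classifier
substitutes a bit-score floor (default 50), since Karlin–Altschul E-value
calibration for arbitrary database sizes is out of scope. Masked symbols
(N/X) never seed and score −4 against everything, so hard-masked regions
cannot anchor or sustain alignments. Because each seed cluster is extended
independently, tandem copies of a query each return their own hit — this
is what the CNV caller relies on. Against a full Smith–Waterman oracle the
windowed identity agrees within ±2 points on randomized mutated pairs (see
the test suite); the heuristic can only miss alignments with no shared
k-mer, i.e. pairs far below every identity threshold used here.

## Origin classification and amplicon groups

Hits are filtered (query coverage > 0.50, identity > 80, E ≤ 1e-20 when
present, else bit score ≥ 50); the subject's contig class then decides the
category: X-only → exclusive gametolog, autosome-only → exclusive paralog,
both → both; any qualifying hit on a sub-100 kb contig makes the transcript
`EXCLUDED_UNCATEGORIZED` regardless of other hits, because that subject's
class is unknowable; no qualifying hits → `NO_HOMOLOG`. Categories are
mutually exclusive and exhaustive by construction.

Amplicon grouping compares concatenated CDS per transcript all-vs-all and
joins a pair passing >95% query coverage and >99.9% identity **in either
direction** — coverage is asymmetric for length-discordant pairs and
reciprocity is not required. Groups are connected components of size ≥2;
the representative is the longest member (ties lexicographic). The
accounting `unique = total − ampliconic + n_groups` is a tested invariant
for every input. Enrichment of gametologs vs paralogs normalizes counts by
class size — assembled bp by default; total transcript counts can be passed
as the sizes instead, which is the same operation on a different 2×2 table.

## Exact 2×2 inference

Conditioned on both margins, the focal cell follows Fisher's noncentral
hypergeometric distribution with noncentrality ψ (the odds ratio). The
package reports, matching R's `fisher.test` conventions:

- **p (two-sided)** at ψ = 1 by point-probability ordering: the total mass
  of outcomes no more probable than the observed one (relative tie
  tolerance 1e-7);
- **conditional MLE of ψ**: the root of E_ψ[A] = a, solved by monotone
  bracket expansion on log ψ plus Brent's method (xtol 1e-11);
- **central CI**: inversion of the two one-sided exact tail tests at
  (1−conf)/2 each; a focal cell at the edge of its support yields a 0 or
  +∞ bound rather than an error. A zero *margin* is an error — the odds
  ratio is undefined.

All tail sums are computed in log space from log-gamma binomial
coefficients, vectorized over the full conditional support; a support of
~2.8 million values (shared-SNP counts over 1.15 Gb vs 58.6 Mb) completes
in seconds. Against exhaustive enumeration with exact integer arithmetic,
p-values agree to 1e-10 and the returned CI bounds satisfy their defining
tail equations to 1e-8 for every table with all margins ≤ 30. On one
published-scale table the CI upper bound differs from R's printed value in
the second decimal (30.540 vs 30.568); evaluating R's own `dhyper` tail at
both candidates shows 30.540 is the exact root and the discrepancy is R's
default `uniroot` tolerance.

## Variant partitioning

Sites are kept if they are biallelic SNVs with both lines' depth inside
[5, 65] (bounds inclusive); drops are counted by reason, and a missing DP
drops the site under `no_depth`. Categories: **fixed SNV** — both lines
homozygous for different alleles; **shared SNP** — the same polymorphism in
both lines, by default both lines heterozygous (`het_in_both`). The lines
were sequenced as male pools, so genotype semantics are a choice:
`allele_in_both` (both alleles observed in each line's genotype) is
available as a config alternative. Everything else — missing genotype,
polymorphism confined to one line — is `OTHER`. The three categories
partition the retained sites exactly.

Density enrichment builds, per chromosome class, the 2×2 table
[count, class length − count] and applies the exact machinery above; the
caller chooses which assembly-length column to use for class lengths (the
reference haplotype's contigs by default — the coordinates the calls were
made on).

The cis window flags a gene when ≥1 fixed SNV lies in
[gene start − 2 kb, gene end + 2 kb], inclusive at both boundaries and
clipped to the contig; each gene counts once. Flagging is strand-agnostic
(regulatory sequence flanks both sides) but each SNV's label — genic,
upstream, downstream, intergenic — is strand-aware and taken from the
nearest qualifying gene, genic taking precedence. Enlarging the flank can
only add flagged genes (tested monotonicity).

## CNV detection and exon profiles

Each exon of the probe gene is searched against the target contig on both
strands; hits ≥80% identity are sorted by contig position and grouped into
copy units, starting a new unit when the gap to the previous hit exceeds
`max_intra_copy_gap` (default 50 kb — tandem copies are consecutive but the
spacer length is unconstrained), when orientation flips, or when the exon
order resets (an earlier exon after a later one marks the next tandem
copy). A unit with ≥3 non-absent exons is a copy. Per-exon status comes
from the aligned fraction of the exon: ≥0.8 present, 0.2–0.8 partial,
else absent — the thresholds are artifact conventions for "partial", which
real annotations rarely quantify. Copies are reported 5'→3' in contig
orientation. Statuses are invariant to where the copy sits in the contig.

Exonic vs noncoding divergence between two gene regions is measured on
complementary hard-masked inputs: once with everything but exons masked,
once with exons masked. Each unmasked block of region A is aligned
separately against the masked region B and the best alignments are pooled
into one identity and one aligned fraction per component; blocks with no
alignment at all are the reported unaligned gaps. A fully masked component
is undefined (`None`), never 0.

## Genealogy

Gene copies at >99% identity are compared by neighbor-joining on
Jukes–Cantor distances (d = −¾ ln(1 − 4p/3) over pairwise non-gap columns;
saturated pairs are capped at 5 substitutions/site). This distance tree
stands in for a maximum-likelihood tree: at this divergence the two agree
topologically at a fraction of the cost, and the approximation is accepted
as a design choice. Sequences of unequal length are star-aligned to the
longest by global pairwise alignment, projecting onto its columns —
adequate for near-identical copies, not a general MSA. Supports are
site-resampling bootstrap percentages (default 100 replicates, seeded and
reproducible) attached to each internal bipartition of the point tree.
A tree whose internal branches are all ~0 is flagged star-like rather than
presented as resolved.

## Synthetic data generator

The generator emulates the study design the pipeline targets: an inbred
background shared by two Y introgression lines that differ only in their Y
haplotype. It plants, with every coordinate and label recorded as truth:
autosomal contigs, one X, two Y haplotype contigs sharing their core
sequence, and sub-100 kb contigs; Y genes with X gametolog copies,
autosomal paralog copies, both, neither, and one gene with an extra copy on
a short contig; ampliconic families at >99.9% identity; fixed SNVs applied
to the Y_L core only (the X plants none, matching the two-line design);
shared heterozygous SNPs on autosomes and X at per-bp rates defaulting to
the densities observed between two real introgression lines (~2.4e-3/bp
autosomal, ~8.2e-5/bp on X, fixed ~2.6e-4/bp on Y); and a candidate growth
gene — complete (25 exons) on an autosome, and as tandem truncated copies
(exons 1–5 missing, exon 6 halved to its 3' part, a generator convention
since the real breakpoint is unobserved) with configurable copy number per
haplotype (defaults 3 vs 1).

Background sequence is i.i.d. uniform — repeat realism is out of scope;
the identity thresholds of the classifiers are what matter. Protein
identity of planted homolog copies is made exact by codon-level mutation
(each selected codon is swapped for one encoding a different amino acid),
so the >80% filter operates at a controlled margin (defaults 0.90
gametolog, 0.88 paralog).

Per-contig mean depth per sample is drawn from a **Gamma** distribution
with mean μ = mean_depth × ploidy factor and squared coefficient of
variation `depth_dispersion` — the mixing distribution of a
negative-binomial read count, which is the natural model for a depth
*averaged over a long contig* and degenerates to exactly μ at dispersion 0,
enabling exact noiseless tests. The default dispersion is 0.02 (14% CV),
the realistic scale for library-normalized coverage over ≥100 kb contigs;
robustness examples use 0.3 (55% CV). Females receive a Y mismapping floor
ε (default 0.01 of mean depth) — a free parameter, not an estimate, since
real female Y mismapping levels are design-specific. Per-site variant
depths are Poisson around the mean with a configurable fraction planted
outside [5, 65] to exercise the depth filter.

Determinism: one master seed fans out to per-stage child seeds through
`numpy` seed sequences; identical seed and config give byte-identical
FASTA/GFF3/VCF/TSV output.

What passing on synthetic data does **not** show: robustness to repeats,
mappability artifacts, assembly fragmentation or collapsed duplications;
calibration of the coverage model against any real library; or that the
aligner's heuristics match BLAST on remote homology. It does show the
statistical machinery, the classification logic, the coordinate handling
and the copy/exon calling are correct under the stated model.

## Problem sizes used in tests

The shipped test suite and acceptance script run the default-scale design
(six 250 kb autosomes, 150 kb X, ~150–185 kb Y haplotypes) for coverage and
variant recovery, a trimmed gene catalogue for the homology stages, 50
seeded genomes for copy-number recovery, 100 seeded genealogy replicates
with 100 bootstraps each, and the complete enumeration of 2×2 tables with
margins ≤ 30 (164,176 tables) against the exact oracle. These sizes were
chosen so the full suite completes in a few minutes while every claim is
still exercised end to end.

## Known limitations

- The aligner indexes k-mers in Python dictionaries; fine for hundreds of
  kilobases per contig, not for chromosome-scale FASTA.
- E-values are only honored from external BLAST tables; the internal
  aligner's bit-score floor is a proxy, not a calibrated significance.
- The star alignment in the genealogy drops insertions relative to the
  reference sequence; for copies with large indels a real MSA should be
  substituted upstream.
- `shared SNP` semantics for pooled sequencing are a convention
  (`het_in_both` default); with individual genotypes reconsider
  `allele_in_both`.
- The sex-assignment vote assumes at least one X- or Y-like contig among
  the most variable ones; a genome with no sex chromosomes yields an
  arbitrary split flagged only by the downstream absence of X/Y calls.
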