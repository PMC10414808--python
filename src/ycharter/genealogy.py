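"""Distance-based genealogy of near-identical gene copies with bootstrap.

For gene copies at >99% identity a neighbor-joining tree on Jukes-Cantor
distances recovers the same topology as likelihood methods at a fraction of
the cost, and is the approximation used here.  Support values come from
site-resampling bootstrap: each replicate redraws alignment columns with
replacement, rebuilds the NJ tree, and each internal bipartition of the
point-estimate tree is annotated with the percentage of replicates that
contain it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = ["GeneTree", "align_near_identical", "jukes_cantor_distances", "build_genealogy"]


@dataclass
class GeneTree:
    tree: "TreeNode"                      # NJ tree with branch lengths (subs/site)
    leaves: tuple[str, ...]
    supports: dict[frozenset[str], float]  # bipartition -> bootstrap %
    n_bootstrap: int
    star_like: bool                        # all internal branches ~0

    def newick(self) -> str:
        return str(self.tree)

    def support_for(self, clade: set[str]) -> float | None:
        """Bootstrap % of the bipartition separating ``clade`` from the rest."""
        key = self._canonical(frozenset(clade))
        return self.supports.get(key)

    def _canonical(self, side: frozenset[str]) -> frozenset[str]:
        ref = min(self.leaves)
        return side if ref not in side else frozenset(self.leaves) - side


def align_near_identical(seqs: dict[str, str]) -> dict[str, str]:
    """Equal-length alignment of near-identical sequences.

    Sequences already sharing one length are stacked as-is.  Otherwise each
    sequence is globally aligned to the longest one and projected onto its
    columns (insertions relative to the reference are dropped) — a star
    alignment that is adequate at the >99% identity these gene copies show.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return dict(seqs)
    from Bio import Align

    ref_name = max(seqs, key=lambda k: (len(seqs[k]), k))
    ref = seqs[ref_name]
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-2,
    )
    out = {}
    for name, seq in seqs.items():
        if name == ref_name:
            out[name] = ref
            continue
        aln = aligner.align(ref, seq)[0]
        cols = ["-"] * len(ref)
        for (rs, re), (qs, qe) in zip(*aln.aligned):
            for k in range(re - rs):
                cols[rs + k] = seq[qs + k]
        out[name] = "".join(cols)
    return out


def jukes_cantor_distances(aligned: dict[str, str]) -> DistanceMatrix:
    """JC69 distances d = -3/4 ln(1 - 4p/3) over pairwise non-gap columns."""
    names = sorted(aligned)
    arrs = {n: np.frombuffer(aligned[n].upper().encode(), dtype=np.uint8) for n in names}
    valid = {n: np.isin(arrs[n], np.frombuffer(b"ACGT", dtype=np.uint8)) for n in names}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[names[i]] & valid[names[j]]
            tot = int(both.sum())
            if tot == 0:
                raise ValueError(f"no comparable sites between {names[i]} and {names[j]}")
            p = float((arrs[names[i]][both] != arrs[names[j]][both]).sum()) / tot
            if p >= 0.749999:
                dist = 5.0  # saturated; beyond JC's resolvable range
            else:
                dist = -0.75 * math.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=names)


def _bipartitions(tree: TreeNode, leaves: frozenset[str], ref: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized to the side without ``ref``."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = leaves - side
        out.add(side)
    return out


def _nj(dm: DistanceMatrix) -> TreeNode:
    tree = nj(dm)
    # root at the first leaf's parent edge for a stable traversal
    return tree


def build_genealogy(
    seqs: dict[str, str],
    n_bootstrap: int = 100,
    seed: int = 0,
) -> GeneTree:
    """Neighbor-joining genealogy with site-resampling bootstrap supports.

    ``seqs`` maps region label to its concatenated CDS; sequences are
    aligned (see :func:`align_near_identical`), JC distances computed, the
    NJ tree built, and ``n_bootstrap`` column-resampled replicates scored.
    Three or more sequences are required.  A tree whose internal branches
    are all ~0 is flagged ``star_like``.
    """
    if len(seqs) < 3:
        raise ValueError(f"need at least 3 sequences, got {len(seqs)}")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    aligned = align_near_identical(seqs)
    names = sorted(aligned)
    leaves = frozenset(names)
    ref = min(names)
    mat = np.vstack(
        [np.frombuffer(aligned[n].upper().encode(), dtype=np.uint8) for n in names]
    )
    n_sites = mat.shape[1]

    def tree_from_columns(m: np.ndarray) -> TreeNode:
        al = {name: m[i].tobytes().decode() for i, name in enumerate(names)}
        return _nj(jukes_cantor_distances(al))

    point = tree_from_columns(mat)
    point_parts = _bipartitions(point, leaves, ref)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    hits = {part: 0 for part in point_parts}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_sites, size=n_sites)
        parts = _bipartitions(tree_from_columns(mat[:, cols]), leaves, ref)
        for part in point_parts:
            if part in parts:
                hits[part] += 1
    supports = {p: 100.0 * h / n_bootstrap for p, h in hits.items()}

    internal_lengths = [
        node.length or 0.0 for node in point.non_tips(include_self=False)
    ]
    star_like = all(l < 1e-9 for l in internal_lengths) if internal_lengths else True

    # annotate supports onto internal node names for newick output
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if ref not in side else leaves - side
        if canon in supports:
            node.name = f"{supports[canon]:.0f}"

    return GeneTree(
        tree=point,
        leaves=tuple(names),
        supports=supports,
        n_bootstrap=n_bootstrap,
        star_like=star_like,
    )
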