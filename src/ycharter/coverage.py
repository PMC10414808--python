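"""Sex assignment and sex-linked contig calling from read-depth tables.

Males are hemizygous XY, so relative to autosomes an X-linked contig shows
a male:female normalized depth ratio near 0.5:1 and a Y-linked contig near
1:0.  The caller normalizes each sample by its median depth over long
contigs (absorbing library size), identifies the XX and XY sample groups by
2-means clustering on the most variable contigs, and tests each contig with
a Welch t-test; contigs passing the significance and relative-difference
gates are classified X or Y by their depth ratio.  Contigs under the length
gate are never called (their class cannot be established with confidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageMatrix",
    "SexLinkageCall",
    "normalize_coverage",
    "assign_sample_sex",
    "call_sex_linked_contigs",
]

DEFAULT_MIN_CONTIG_LEN = 100_000


@dataclass
class CoverageMatrix:
    """Normalized depth per (contig, sample) with contig lengths.

    ``depth`` is contigs x samples; ``sex`` maps sample to declared or
    inferred label ('male'/'female'), possibly empty before assignment.
    """

    depth: pd.DataFrame
    lengths: pd.Series
    sex: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    @property
    def contigs(self) -> list[str]:
        return list(self.depth.index)


@dataclass
class SexLinkageCall:
    contig: str
    length: int
    male_mean: float
    female_mean: float
    ratio: float            # male : female
    t_stat: float
    p_value: float
    rel_diff: float         # |M - F| / max(M, F)
    call: str               # AUTOSOME / X / Y / SHORT / AMBIGUOUS


def normalize_coverage(
    raw: pd.DataFrame, min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    lengths: pd.Series | dict | None = None,
) -> CoverageMatrix:
    """Divide each sample's depths by its median over long contigs.

    ``raw`` is the tidy table (contig, sample, sex, mean_depth); ``lengths``
    gives contig lengths (contigs absent from it are treated as long when
    the table is the only information available).  The input table is not
    modified.
    """
    required = {"contig", "sample", "mean_depth"}
    if not required <= set(raw.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    wide = raw.pivot_table(index="contig", columns="sample", values="mean_depth")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing depth values for samples {missing}")
    if wide.shape[1] < 2:
        raise ValueError("need at least two samples")
    if lengths is None:
        lengths = pd.Series(np.iinfo(np.int64).max, index=wide.index)
    else:
        lengths = pd.Series(lengths).reindex(wide.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()
            raise ValueError(f"no length supplied for contigs {missing}")
    long_contigs = lengths.index[lengths >= min_contig_len]
    if len(long_contigs) == 0:
        raise ValueError(f"no contig reaches min_contig_len={min_contig_len}")
    medians = wide.loc[long_contigs].median(axis=0)
    zero = medians.index[medians == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with all-zero depth over long contigs: {zero}")
    norm = wide / medians
    if "sex" in raw.columns:
        sex = raw.drop_duplicates("sample").set_index("sample")["sex"].reindex(norm.columns)
    else:
        sex = pd.Series(index=norm.columns, dtype=object)
    return CoverageMatrix(depth=norm, lengths=lengths.astype("int64"), sex=sex)


def assign_sample_sex(
    matrix: CoverageMatrix,
    candidate_contigs: set[str] | None = None,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Split samples into XY and XX groups by 2-means on variable contigs.

    Clustering uses the normalized depths of ``candidate_contigs`` or, by
    default, the top ``top_frac`` contigs by between-sample variance (at
    least two).  Which cluster is XY is decided by a per-contig vote over
    the selected contigs: where one group's mean depth is a small fraction
    of the other's the contig looks Y-linked and the *depleted* group is XX
    (females carry no Y), while a roughly half-depth group marks an X-linked
    contig and the *lower* group is XY.  Declared labels, when present, are
    compared and a ``mismatch`` flag reported.  Identical samples yield
    AMBIGUOUS calls.
    """
    from sklearn.cluster import KMeans

    depth = matrix.depth
    if depth.shape[1] < 2:
        raise ValueError("need at least two samples to assign sex")
    # work on log depth: a Y-linked contig's female dropout is orders of
    # magnitude, which the log scale turns into the dominant variance signal,
    # while multiplicative sampling noise on autosomes contributes equally
    # everywhere
    log_depth = np.log10(depth + 1e-2)
    if candidate_contigs is not None:
        sel = log_depth.loc[sorted(set(candidate_contigs) & set(depth.index))]
    else:
        variances = log_depth.var(axis=1)
        k = max(2, int(np.ceil(top_frac * len(variances))))
        sel = log_depth.loc[variances.sort_values(ascending=False).index[:k]]
    X = sel.T.to_numpy()
    inferred: pd.Series
    if np.allclose(X, X[0], atol=1e-12):
        inferred = pd.Series("AMBIGUOUS", index=depth.columns)
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        lin = depth.loc[sel.index].T.to_numpy()  # linear depths for the ratio vote
        g0 = lin[km.labels_ == 0].mean(axis=0)
        g1 = lin[km.labels_ == 1].mean(axis=0)
        votes = 0.0  # positive: group 0 is XY
        for m0, m1 in zip(g0, g1):
            lo, hi = sorted((m0, m1))
            if hi <= 0:
                continue
            frac = lo / hi
            low_is_g0 = m0 <= m1
            if frac <= 0.15:           # Y-like: depleted group lacks a Y -> XX
                votes += -1.0 if low_is_g0 else 1.0
            elif 0.3 <= frac <= 0.8:   # X-like: half-depth group is hemizygous -> XY
                votes += 1.0 if low_is_g0 else -1.0
        if votes == 0:  # no informative contig: fall back to overall lower mean
            votes = 1.0 if g0.mean() <= g1.mean() else -1.0
        xy_group = 0 if votes > 0 else 1
        inferred = pd.Series(
            np.where(km.labels_ == xy_group, "male", "female"), index=depth.columns
        )
    declared = matrix.sex.reindex(depth.columns)
    out = pd.DataFrame(
        {
            "sample": depth.columns,
            "inferred_sex": inferred.values,
            "declared_sex": declared.values,
        }
    )
    out["low_confidence"] = (inferred == "male").sum() < 2 or (inferred == "female").sum() < 2
    out["mismatch"] = out["declared_sex"].notna() & (
        out["declared_sex"] != out["inferred_sex"]
    ) & (out["inferred_sex"] != "AMBIGUOUS")
    return out


def _welch(male: np.ndarray, female: np.ndarray) -> tuple[float, float]:
    """Welch t-test robust to the zero-variance (noiseless) corner."""
    if male.var(ddof=1) == 0 and female.var(ddof=1) == 0:
        if male.mean() == female.mean():
            return 0.0, 1.0
        return np.inf if male.mean() > female.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(male, female, equal_var=False)
    return float(t), float(p)


def call_sex_linked_contigs(
    matrix: CoverageMatrix,
    sex_labels: pd.Series | dict,
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
    alpha: float = 0.05,
    min_rel_diff: float = 0.10,
    x_ratio_window: tuple[float, float] = (0.3, 0.7),
    y_female_max: float = 0.1,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Classify each contig as AUTOSOME / X / Y / SHORT / AMBIGUOUS.

    A contig shorter than ``min_contig_len`` is SHORT and never tested.
    Otherwise a Welch t-test compares male and female normalized depths;
    contigs failing ``alpha`` (Bonferroni-adjusted if requested) or whose
    relative difference |M-F|/max(M,F) is below ``min_rel_diff`` are
    AUTOSOME (the conservative gate for weakly diverged contigs).  Passing
    contigs are Y when the female mean is at most ``y_female_max`` times
    the male mean, X when the male:female ratio falls in
    ``x_ratio_window``, else AMBIGUOUS.
    """
    sex = pd.Series(sex_labels)
    males = [s for s in matrix.samples if sex.get(s) == "male"]
    females = [s for s in matrix.samples if sex.get(s) == "female"]
    if len(males) < 2 or len(females) < 2:
        raise ValueError(
            f"need >=2 samples per sex group for the t-test, got "
            f"{len(males)} male / {len(females)} female"
        )
    n_tested = int((matrix.lengths >= min_contig_len).sum())
    alpha_eff = alpha / max(n_tested, 1) if bonferroni else alpha
    calls = []
    for contig in matrix.contigs:
        length = int(matrix.lengths[contig])
        m = matrix.depth.loc[contig, males].to_numpy(dtype=float)
        f = matrix.depth.loc[contig, females].to_numpy(dtype=float)
        m_mean, f_mean = float(m.mean()), float(f.mean())
        ratio = m_mean / f_mean if f_mean > 0 else np.inf
        top = max(m_mean, f_mean)
        rel_diff = abs(m_mean - f_mean) / top if top > 0 else 0.0
        t, p = _welch(m, f)
        if length < min_contig_len:
            call = "SHORT"
        elif p > alpha_eff or rel_diff < min_rel_diff:
            call = "AUTOSOME"
        elif f_mean <= y_female_max * m_mean:
            call = "Y"
        elif x_ratio_window[0] <= ratio <= x_ratio_window[1]:
            call = "X"
        else:
            call = "AMBIGUOUS"
        calls.append(
            SexLinkageCall(
                contig=contig, length=length, male_mean=m_mean, female_mean=f_mean,
                ratio=ratio, t_stat=t, p_value=p, rel_diff=rel_diff, call=call,
            )
        )
    return pd.DataFrame([c.__dict__ for c in calls]).set_index("contig")
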