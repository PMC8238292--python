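"""Count-matrix statistics: normalization, DE, PCA, junction ratios.

Counts are normalized by median-of-ratios size factors and transformed to
log2 counts-per-million with a prior count of 0.5:

    logCPM = log2( (count + 0.5) / (library + 1) * 1e6 )

Differential expression is a per-gene Welch t-test on log-CPM with
Benjamini-Hochberg FDR control across the tested genes; genes failing a
minimum-abundance filter (CPM > 1 in at least half of the smaller group)
are excluded from testing and from the BH denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

PRIOR_COUNT = 0.5


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample are excluded from the reference;
    if no gene qualifies, all factors are 1.
    """
    counts = matrix.to_numpy(float)
    if counts.shape[1] == 0:
        return pd.Series(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        return pd.Series(1.0, index=matrix.columns)
    logs = np.log(counts[positive])
    ref = logs.mean(axis=1)  # log geometric mean per gene
    sf = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns)


def log_cpm(matrix: pd.DataFrame, prior: float = PRIOR_COUNT) -> pd.DataFrame:
    """log2 counts-per-million on size-factor-adjusted counts.

    Normalized counts (count / size factor) are scaled against a *common*
    library size (the mean adjusted library) rather than each sample's own
    adjusted sum: per-sample re-normalization would re-introduce the
    composition bias the median-of-ratios factors remove, shifting every
    null gene when a minority of genes move.
    """
    _validate_matrix(matrix)
    sf = size_factors(matrix)
    adj = matrix.to_numpy(float) / sf.to_numpy()[None, :]
    lib = float(adj.sum(axis=0).mean())
    lcpm = np.log2((adj + prior) / (lib + 1.0) * 1e6)
    return pd.DataFrame(lcpm, index=matrix.index, columns=matrix.columns)


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    libs = matrix.sum(axis=0)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for samples {bad}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    treated: str | None = None,
    control: str | None = None,
    min_cpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log-CPM with BH-FDR.

    ``groups`` maps sample id to group label (two levels).  ``logFC`` is the
    mean log-CPM difference, treated minus control; with no explicit labels
    the lexicographically larger label is treated.  Genes with CPM <=
    ``min_cpm`` in more than half of the smaller group are not tested
    (``tested=False``, NaN statistics) and do not enter the BH denominator.
    """
    groups = pd.Series(groups)
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if control is None and treated is None:
        control, treated = labels
    elif (control is None) != (treated is None):
        raise ValueError("specify both treated and control, or neither")
    t_cols = groups.index[groups == treated]
    c_cols = groups.index[groups == control]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(matrix)
    adj = matrix.to_numpy(float) / sf.to_numpy()[None, :]
    cpm = adj / adj.sum(axis=0).mean() * 1e6
    n_small = min(len(t_cols), len(c_cols))
    need = -(-n_small // 2)  # at least half of the smaller group
    tested = (pd.DataFrame(cpm, index=matrix.index, columns=matrix.columns)
              > min_cpm).sum(axis=1) >= need

    lcpm = log_cpm(matrix)
    a = lcpm[t_cols].to_numpy()
    b = lcpm[c_cols].to_numpy()
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate zero-variance genes: identical means -> p = 1, else 0
    nan = np.isnan(p)
    p[nan & (logfc == 0)] = 1.0
    p[nan & (logfc != 0)] = 0.0

    out = pd.DataFrame({
        "logFC": logfc,
        "logCPM": lcpm.mean(axis=1),
        "p": np.where(tested, p, np.nan),
        "tested": tested,
    }, index=matrix.index)
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "p"])
    return out


def filter_candidates(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    lcpm_min: float = 3.0,
) -> list[str]:
    """Genes with logFC > lfc_min, FDR < fdr_max and logCPM > lcpm_min.

    All inequalities are strict; untested genes never pass.
    """
    keep = (
        (de["logFC"] > lfc_min)
        & (de["fdr"] < fdr_max)
        & (de["logCPM"] > lcpm_min)
    )
    return list(de.index[keep.fillna(False)])


def pca_variance(matrix: pd.DataFrame) -> np.ndarray:
    """Ordered per-component variance fractions of centered log-CPM PCA.

    Samples are observations, genes features; fractions sum to 1 over all
    components.  A constant matrix yields all-zero fractions with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    lcpm = log_cpm(matrix).to_numpy().T  # samples x genes
    centered = lcpm - lcpm.mean(axis=0)
    if np.allclose(centered, 0.0):
        warnings.warn("constant expression matrix: zero variance in PCA")
        return np.zeros(matrix.shape[1] - 1)
    pca = PCA(svd_solver="full")
    pca.fit(centered)
    return pca.explained_variance_ratio_


@dataclass(frozen=True)
class JunctionRatio:
    """Variant-to-canonical splice-junction read ratio with a binomial CI.

    The CI is a Wilson interval on the variant read proportion
    variant / (variant + canonical); ``defined`` is False when no canonical
    reads were observed.
    """

    variant_reads: int
    canonical_reads: int
    ratio: float
    ci_low: float
    ci_high: float
    defined: bool


def junction_ratio(variant_junction_reads: int,
                   canonical_junction_reads: int) -> JunctionRatio:
    """Splice-variant expression ratio, e.g. AR-V7 vs full-length AR."""
    v, c = int(variant_junction_reads), int(canonical_junction_reads)
    if v < 0 or c < 0:
        raise ValueError("junction read counts must be >= 0")
    total = v + c
    if c == 0:
        return JunctionRatio(v, c, float("nan"), float("nan"), float("nan"),
                             defined=False)
    lo, hi = proportion_confint(v, total, alpha=0.05, method="wilson")
    return JunctionRatio(v, c, v / c, float(lo), float(hi), defined=True)
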