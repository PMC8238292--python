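"""FISH copy-state quantification and the prevalence-response correlation.

Each scored cell carries a target-gene probe count and a centromere probe
count (hybridization control).  Cells with no centromere signal fail QC;
QC-pass cells are partitioned into deep deletion (zero target signals),
single-copy loss (one), or two-plus (two or more).  Per-sample state
prevalences get Wilson binomial confidence intervals, and the pretreatment
deep-deletion prevalence is correlated with residual tumor volume by
Spearman rank correlation (exact permutation p-value at small n).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    proportion_confint,
)

STATES = ("deep_deletion", "single_loss", "two_plus")


def classify_cells(cells: pd.DataFrame) -> pd.Series:
    """Per-cell copy state from (target_signals, centromere_signals).

    qc_fail iff centromere = 0; otherwise deep_deletion iff target = 0,
    single_loss iff target = 1, two_plus iff target >= 2.  Every cell maps
    to exactly one state.
    """
    t = cells["target_signals"].to_numpy()
    c = cells["centromere_signals"].to_numpy()
    if (t < 0).any() or (c < 0).any():
        raise ValueError("signal counts must be >= 0")
    state = np.where(
        c == 0, "qc_fail",
        np.where(t == 0, "deep_deletion",
                 np.where(t == 1, "single_loss", "two_plus")),
    )
    return pd.Series(state, index=cells.index, name="state")


@dataclass(frozen=True)
class PrevalenceSummary:
    """Copy-state prevalence of one sample's QC-pass cells."""

    sample_id: str
    n_cells_pass: int
    n_deep_deletion: int
    n_single_loss: int
    n_two_plus: int
    frac_deep_deletion: float
    frac_single_loss: float
    frac_two_plus: float
    ci_deep_deletion: tuple[float, float]
    ci_single_loss: tuple[float, float]
    ci_two_plus: tuple[float, float]
    low_confidence: bool

    def count(self, state: str) -> int:
        return getattr(self, f"n_{state}")

    def frac(self, state: str) -> float:
        return getattr(self, f"frac_{state}")


def prevalence(cells: pd.DataFrame, sample_id: str = "",
               min_cells: int = 50) -> PrevalenceSummary:
    """Per-state prevalence with Wilson 95% CIs among QC-pass cells.

    Samples with fewer than ``min_cells`` passing cells are flagged
    low-confidence rather than rejected.
    """
    state = classify_cells(cells)
    passing = state[state != "qc_fail"]
    n = len(passing)
    if n == 0:
        raise ValueError(f"sample {sample_id!r}: no QC-pass cells")
    counts = {s: int((passing == s).sum()) for s in STATES}
    fracs = {s: counts[s] / n for s in STATES}
    cis = {}
    for s in STATES:
        lo, hi = proportion_confint(counts[s], n, alpha=0.05, method="wilson")
        cis[s] = (float(lo), float(hi))
    low = n < min_cells
    if low:
        warnings.warn(
            f"sample {sample_id!r}: only {n} QC-pass cells (< {min_cells}); "
            "prevalence flagged low-confidence"
        )
    return PrevalenceSummary(
        sample_id=sample_id,
        n_cells_pass=n,
        n_deep_deletion=counts["deep_deletion"],
        n_single_loss=counts["single_loss"],
        n_two_plus=counts["two_plus"],
        frac_deep_deletion=fracs["deep_deletion"],
        frac_single_loss=fracs["single_loss"],
        frac_two_plus=fracs["two_plus"],
        ci_deep_deletion=cis["deep_deletion"],
        ci_single_loss=cis["single_loss"],
        ci_two_plus=cis["two_plus"],
        low_confidence=low,
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    norm = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if norm == 0:
        return float("nan")
    perms = np.array(list(itertools.permutations(range(len(y)))), dtype=np.int8)
    rho_all = ry[perms] @ rx / norm
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def response_correlation(
    prevalences,
    residual_volumes,
    exact_n_max: int = 10,
) -> tuple[float, float]:
    """Spearman correlation of copy-state prevalence vs residual volume.

    Inputs are aligned sequences, or dicts keyed by patient (aligned on the
    shared keys).  Requires >= 4 patients.  Returns ``(rho, p)`` with an
    exact two-sided permutation p-value for n <= ``exact_n_max`` and the
    asymptotic p otherwise.  A constant prevalence (or volume) vector gives
    ``(nan, nan)`` with a warning.
    """
    if isinstance(prevalences, dict) and isinstance(residual_volumes, dict):
        keys = sorted(set(prevalences) & set(residual_volumes))
        x = np.asarray([prevalences[k] for k in keys], dtype=float)
        y = np.asarray([residual_volumes[k] for k in keys], dtype=float)
    else:
        x = np.asarray(list(prevalences), dtype=float)
        y = np.asarray(list(residual_volumes), dtype=float)
        if len(x) != len(y):
            raise ValueError("prevalence and volume vectors differ in length")
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 patients with both measurements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant measurement vector: correlation undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_n_max:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def pre_post_change(pre: PrevalenceSummary,
                    post: PrevalenceSummary) -> pd.DataFrame:
    """Per-state prevalence change (post minus pre) with two-proportion CIs."""
    if pre is None or post is None:
        raise ValueError("both pre- and post-treatment summaries are required")
    rows = []
    for s in STATES:
        delta = post.frac(s) - pre.frac(s)
        lo, hi = confint_proportions_2indep(
            post.count(s), post.n_cells_pass,
            pre.count(s), pre.n_cells_pass,
            compare="diff", method="newcomb",
        )
        rows.append((s, pre.frac(s), post.frac(s), delta,
                     float(lo), float(hi)))
    return pd.DataFrame(
        rows,
        columns=["state", "frac_pre", "frac_post", "delta",
                 "ci_low", "ci_high"],
    )
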