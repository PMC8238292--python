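"""Clonal dynamics: CCF clustering, longitudinal matching, segment pairs.

Clonal populations are recovered per sample by a finite binomial-mixture
model over alt read counts.  Each component is parameterized by a single
cancer cell fraction ``ccf_c``; variant *i* in component *c* contributes

    alt_i ~ Binomial(depth_i, w_i * ccf_c),   w_i = rho*m_i / (rho*CNt_i + 2(1-rho))

where ``w_i`` is the variant's expected VAF per unit CCF under its purity
and local copy state.  EM maximizes the mixture likelihood; the number of
components is selected by BIC over 1..k_max.  This is a deliberately
desk-scale, deterministic stand-in for Dirichlet-process clonal
reconstruction tools: it supports the same qualitative pre/post-treatment
comparison (which clones grew, shrank, emerged or went extinct) without
MCMC.

Clusters from the pre- and post-treatment sample of a patient are matched
greedily by nearest CCF; matched pairs are labelled stable / growing /
shrinking by a configurable CCF-shift threshold, and unmatched clusters
are emerging (post only) or extinct (pre only).

An orthogonal copy-number comparison matches segments across timepoints by
reciprocal genomic overlap and summarizes the paired copy-number fractions
(2D kernel density plus the fraction of loss segments shifting by more
than a threshold).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from neoclone.somatic import is_loss

_EPS = 1e-9
CCF_MAX = 1.5


class BinomialMixtureCCF(BaseEstimator):
    """Finite binomial mixture over alt counts with CCF-valued components.

    Parameters
    ----------
    n_components : int
        Number of mixture components (clones); capped at the number of
        observations.
    max_iter, tol : EM stopping rule (absolute log-likelihood increase).
    random_state : seed of the k-means++-style initialization on CCF point
        estimates; fixed seed makes the fit deterministic.

    Attributes (after ``fit``)
    --------------------------
    ccfs_ : (k,) component cancer cell fractions.
    weights_ : (k,) mixing proportions.
    labels_ : (n,) hard assignments.
    log_likelihood_ : final mixture log-likelihood.
    loglik_path_ : per-iteration log-likelihood (non-decreasing).
    bic_ : Bayesian information criterion of the fit.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 200,
                 tol: float = 1e-8, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        """Fit on X = (alt_count, depth, vaf_weight) rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (alt_count, depth, vaf_weight)")
        alt, depth, w = X[:, 0], X[:, 1], X[:, 2]
        if np.any(depth <= 0) or np.any(w <= 0):
            raise ValueError("depth and vaf_weight must be positive")
        n = len(alt)
        k = min(self.n_components, n)
        ccf_hat = np.clip(alt / depth / w, 0.0, CCF_MAX)
        ccf_hi = min(CCF_MAX, (1.0 - 1e-6) / w.max())

        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    random_state=self.random_state)
        lab0 = km.fit_predict(ccf_hat[:, None])
        ccfs = np.clip(km.cluster_centers_.ravel(), 1e-4, ccf_hi)
        pis = np.bincount(lab0, minlength=k) / n

        log_binom = _log_binom_coef(depth, alt)  # constant in parameters
        path = []
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            # E-step
            p = np.clip(w[:, None] * ccfs[None, :], _EPS, 1 - _EPS)
            log_comp = (log_binom[:, None] + alt[:, None] * np.log(p)
                        + (depth - alt)[:, None] * np.log1p(-p))
            log_w = np.log(np.maximum(pis, _EPS))[None, :] + log_comp
            ll_i = _logsumexp(log_w)
            ll = float(ll_i.sum())
            path.append(ll)
            gamma = np.exp(log_w - ll_i[:, None])
            if ll - prev_ll < self.tol and len(path) > 1:
                break
            prev_ll = ll
            # M-step
            pis = gamma.mean(axis=0)
            ccfs = _mstep_ccf_all(alt, depth, w, gamma, ccfs, ccf_hi)

        self.ccfs_ = ccfs
        self.weights_ = pis
        self.labels_ = np.argmax(gamma, axis=1)
        self.responsibilities_ = gamma
        self.log_likelihood_ = path[-1]
        self.loglik_path_ = np.asarray(path)
        n_params = 2 * k - 1
        self.bic_ = -2.0 * path[-1] + n_params * np.log(n)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        alt, depth, w = X[:, 0], X[:, 1], X[:, 2]
        p = np.clip(w[:, None] * self.ccfs_[None, :], _EPS, 1 - _EPS)
        log_w = (np.log(np.maximum(self.weights_, _EPS))[None, :]
                 + alt[:, None] * np.log(p)
                 + (depth - alt)[:, None] * np.log1p(-p))
        return np.argmax(log_w, axis=1)


def _log_binom_coef(n, k):
    from scipy.special import gammaln
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _logsumexp(a):
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _mstep_ccf_all(alt, depth, w, gamma, ccfs, ccf_hi):
    """Per-component 1-D maximizers of the expected complete-data
    log-likelihood, by safeguarded Newton on the (concave) score.

    The update never decreases a component's objective: a candidate that
    does is discarded in favor of the incumbent, which keeps the EM
    log-likelihood monotone.
    """

    def obj(c):  # (k,) -> per-component weighted binomial log-likelihood
        p = np.clip(w[:, None] * c[None, :], _EPS, 1 - _EPS)
        return np.sum(gamma * (alt[:, None] * np.log(p)
                               + (depth - alt)[:, None] * np.log1p(-p)),
                      axis=0)

    # moment start: exact MLE when all w equal, good elsewhere
    denom = np.maximum(gamma.T @ (depth * w), _EPS)
    cand = np.clip((gamma.T @ alt) / denom, 1e-6, ccf_hi)
    for _ in range(40):
        p = np.clip(w[:, None] * cand[None, :], _EPS, 1 - _EPS)
        score = np.sum(gamma * (alt[:, None] / cand[None, :]
                                - (depth - alt)[:, None] * w[:, None]
                                / (1 - p)), axis=0)
        hess = -np.sum(gamma * (alt[:, None] / cand[None, :] ** 2
                                + (depth - alt)[:, None] * w[:, None] ** 2
                                / (1 - p) ** 2), axis=0)
        step = score / np.minimum(hess, -_EPS)
        cand = np.clip(cand - step, 1e-6, ccf_hi)
        if np.max(np.abs(step)) < 1e-12:
            break
    better = obj(cand) >= obj(ccfs)
    return np.where(better, cand, ccfs)


def cluster_ccfs(ccf_table: pd.DataFrame, k_max: int = 6,
                 seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster a sample's CCF estimates into clones; K selected by BIC.

    ``ccf_table`` is the output of
    :func:`neoclone.somatic.estimate_ccf_table` (needs ``alt_count``,
    ``ref_count`` and ``p_per_ccf``).  Requires >= 5 estimates; ``k_max``
    is capped at the number of estimates.

    Returns ``(clusters, labels)`` where ``clusters`` has one row per clone
    (cluster, mean_ccf, n_variants) sorted by descending CCF.
    """
    if len(ccf_table) < 5:
        raise ValueError("need >= 5 CCF estimates to cluster")
    alt = ccf_table["alt_count"].to_numpy(float)
    depth = alt + ccf_table["ref_count"].to_numpy(float)
    w = ccf_table["p_per_ccf"].to_numpy(float)
    X = np.c_[alt, depth, w]
    k_max = min(k_max, len(ccf_table))
    best = None
    for k in range(1, k_max + 1):
        model = BinomialMixtureCCF(n_components=k, random_state=seed).fit(X)
        if best is None or model.bic_ < best.bic_:
            best = model
    labels = best.labels_
    rows = []
    for c in np.unique(labels):
        rows.append((int(c), float(best.ccfs_[c]), int((labels == c).sum())))
    clusters = pd.DataFrame(rows, columns=["cluster", "mean_ccf", "n_variants"])
    clusters = clusters.sort_values("mean_ccf", ascending=False,
                                    ignore_index=True)
    return clusters, labels


def match_longitudinal(pre_clusters, post_clusters,
                       delta: float = 0.1) -> pd.DataFrame:
    """Greedy nearest-CCF matching of clones across timepoints.

    Accepts cluster tables (columns ``mean_ccf`` and optionally
    ``n_variants``) or plain sequences of CCFs.  Links are one-to-one,
    chosen by smallest |CCF difference| (ties favor larger clusters).
    Matched pairs with |delta_ccf| <= ``delta`` are ``stable``, otherwise
    ``growing``/``shrinking`` by sign; unmatched pre-treatment clones are
    ``extinct`` and unmatched post-treatment clones ``emerging``.
    """
    pre = _as_cluster_frame(pre_clusters)
    post = _as_cluster_frame(post_clusters)
    links = []
    for i, prow in pre.iterrows():
        for j, qrow in post.iterrows():
            d = qrow["mean_ccf"] - prow["mean_ccf"]
            size = prow["n_variants"] + qrow["n_variants"]
            links.append((abs(d), -size, i, j, d))
    links.sort()
    used_pre, used_post = set(), set()
    rows = []
    for _, _, i, j, d in links:
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        if abs(d) <= delta:
            direction = "stable"
        else:
            direction = "growing" if d > 0 else "shrinking"
        rows.append((i, j, pre.loc[i, "mean_ccf"], post.loc[j, "mean_ccf"],
                     d, direction))
    for i in pre.index:
        if i not in used_pre:
            rows.append((i, None, pre.loc[i, "mean_ccf"], np.nan,
                         -pre.loc[i, "mean_ccf"], "extinct"))
    for j in post.index:
        if j not in used_post:
            rows.append((None, j, np.nan, post.loc[j, "mean_ccf"],
                         post.loc[j, "mean_ccf"], "emerging"))
    return pd.DataFrame(
        rows,
        columns=["pre_cluster", "post_cluster", "pre_ccf", "post_ccf",
                 "delta_ccf", "direction"],
    )


def _as_cluster_frame(clusters) -> pd.DataFrame:
    if isinstance(clusters, pd.DataFrame):
        df = clusters.copy()
        if "n_variants" not in df.columns:
            df["n_variants"] = 1
        return df.reset_index(drop=True)
    ccfs = list(clusters)
    return pd.DataFrame({"mean_ccf": ccfs, "n_variants": [1] * len(ccfs)})


def compare_segment_pairs(
    pre_segments: pd.DataFrame,
    post_segments: pd.DataFrame,
    min_reciprocal_overlap: float = 0.5,
    ploidy: float = 2.0,
    shift_threshold: float = 0.25,
):
    """Pair copy-number segments across timepoints by reciprocal overlap.

    Returns ``(pairs, shift_stat, kde)``: ``pairs`` holds one row per
    matched segment with the pre/post copy-number fractions; ``shift_stat``
    is the fraction of matched *loss* segments whose copy-number fraction
    moved by more than ``shift_threshold`` (NaN when no loss segment
    matched); ``kde`` is a dict with a 2D kernel-density grid for plotting
    (None when degenerate).
    """
    if pre_segments.empty or post_segments.empty:
        raise ValueError("both timepoints must have segments")
    rows = []
    for chrom, pre_c in pre_segments.groupby(pre_segments["chrom"].astype(str)):
        post_c = post_segments[post_segments["chrom"].astype(str) == chrom]
        if post_c.empty:
            continue
        for p in pre_c.itertuples(index=False):
            best = None
            for q in post_c.itertuples(index=False):
                ov = min(p.end, q.end) - max(p.start, q.start)
                if ov <= 0:
                    continue
                if (ov / (p.end - p.start) < min_reciprocal_overlap
                        or ov / (q.end - q.start) < min_reciprocal_overlap):
                    continue
                if best is None or ov > best[0]:
                    best = (ov, q)
            if best is not None:
                q = best[1]
                rows.append((
                    chrom, p.start, p.end, q.start, q.end,
                    p.cn_fraction, q.cn_fraction,
                    is_loss(p.major_cn, p.minor_cn, ploidy),
                ))
    pairs = pd.DataFrame(
        rows,
        columns=["chrom", "pre_start", "pre_end", "post_start", "post_end",
                 "cn_fraction_pre", "cn_fraction_post", "is_loss_pre"],
    )
    if pairs.empty:
        return pairs, float("nan"), None
    loss = pairs[pairs["is_loss_pre"]]
    if loss.empty:
        shift = float("nan")
    else:
        moved = (loss["cn_fraction_post"] - loss["cn_fraction_pre"]).abs()
        shift = float((moved > shift_threshold).mean())
    kde = None
    if len(pairs) >= 3:
        xy = pairs[["cn_fraction_pre", "cn_fraction_post"]].to_numpy().T
        try:
            k = stats.gaussian_kde(xy)
            grid = np.linspace(0, 1, 50)
            gx, gy = np.meshgrid(grid, grid)
            dens = k(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
            kde = {"x": grid, "y": grid, "density": dens}
        except np.linalg.LinAlgError:
            kde = None
    return pairs, shift, kde


def plot_segment_pairs(pairs: pd.DataFrame, kde: dict | None,
                       path: str) -> None:
    """Scatter of pre vs post copy-number fractions with density contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pairs["cn_fraction_pre"], pairs["cn_fraction_post"],
               s=12, alpha=0.6, color="k")
    if kde is not None:
        ax.contour(kde["x"], kde["y"], kde["density"], colors="c",
                   linewidths=0.8)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("copy-number fraction (pre)")
    ax.set_ylabel("copy-number fraction (post)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
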