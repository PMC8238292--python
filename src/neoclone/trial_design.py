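"""Exact Simon two-stage phase II design search.

A Simon two-stage design ``(r1/n1, r/n)`` enrolls ``n1`` patients in stage 1;
if at most ``r1`` responses are seen, the trial stops for futility, otherwise
accrual continues to ``n`` patients in total, and the null hypothesis
(response probability ``p0``) is rejected when the total number of responses
exceeds ``r``.  All operating characteristics are exact binomial
convolutions; the design search is an exhaustive enumeration over
``(r1, n1, r, n)`` with ``n <= n_max``, returning both the *optimal* design
(minimum expected sample size under ``p0``) and the *minimax* design
(minimum maximum sample size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom


@dataclass(frozen=True)
class SimonDesign:
    """A two-stage design with its exact operating characteristics.

    Attributes
    ----------
    r1, n1 : int
        Stage-1 futility bound and sample size: stop if responses <= ``r1``.
    r, n : int
        Final rejection bound and maximum sample size: reject H0 iff total
        responses >= ``r + 1``.
    alpha_actual : float
        Exact type I error (rejection probability at ``p0``).
    power_actual : float
        Exact power (rejection probability at ``p1``).
    pet0 : float
        Probability of early termination under ``p0``.
    en0 : float
        Expected sample size under ``p0``.
    """

    r1: int
    n1: int
    r: int
    n: int
    alpha_actual: float = field(default=math.nan, compare=False)
    power_actual: float = field(default=math.nan, compare=False)
    pet0: float = field(default=math.nan, compare=False)
    en0: float = field(default=math.nan, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.r1 <= self.n1 < self.n):
            raise ValueError(
                f"require 0 <= r1 <= n1 < n, got r1={self.r1}, n1={self.n1}, n={self.n}"
            )
        if not (self.r1 <= self.r <= self.n):
            raise ValueError(
                f"require r1 <= r <= n, got r1={self.r1}, r={self.r}, n={self.n}"
            )

    def to_dict(self) -> dict:
        return {
            "r1": self.r1,
            "n1": self.n1,
            "r": self.r,
            "n": self.n,
            "alpha_actual": self.alpha_actual,
            "power_actual": self.power_actual,
            "pet0": self.pet0,
            "en0": self.en0,
        }

    def __str__(self) -> str:  # e.g. "0/9, 2/17"
        return f"{self.r1}/{self.n1}, {self.r}/{self.n}"


def reject_probability(design: SimonDesign, p: float) -> float:
    """Exact probability that the design rejects H0 at response probability p.

    Rejection requires passing stage 1 (stage-1 responses ``x1 > r1``) and
    total responses ``> r``:

        sum_{x1=r1+1..n1} Binom(x1; n1, p) * P(X2 > r - x1; n - n1, p)
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n2 = design.n - design.n1
    x1 = np.arange(design.r1 + 1, design.n1 + 1)
    stage1 = binom.pmf(x1, design.n1, p)
    # binom.sf(k) = P(X > k); sf of a negative bound is 1, beyond n2 is 0.
    stage2 = binom.sf(design.r - x1, n2, p)
    return float(np.sum(stage1 * stage2))


def early_termination(design: SimonDesign, p: float) -> tuple[float, float]:
    """Early-termination probability and expected sample size at p.

    Returns ``(pet, en)`` where ``pet = P(X1 <= r1)`` and
    ``en = n1 + (1 - pet) * (n - n1)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    pet = float(binom.cdf(design.r1, design.n1, p))
    en = design.n1 + (1.0 - pet) * (design.n - design.n1)
    return pet, en


def _evaluate(r1: int, n1: int, r: int, n: int, p0: float, p1: float) -> SimonDesign:
    """Build a design with its operating characteristics filled in."""
    d = SimonDesign(r1=r1, n1=n1, r=r, n=n)
    pet0, en0 = early_termination(d, p0)
    return SimonDesign(
        r1=r1,
        n1=n1,
        r=r,
        n=n,
        alpha_actual=reject_probability(d, p0),
        power_actual=reject_probability(d, p1),
        pet0=pet0,
        en0=en0,
    )


def search_designs(
    p0: float,
    p1: float,
    alpha: float,
    beta: float,
    n_max: int = 60,
) -> tuple[SimonDesign, SimonDesign]:
    """Exhaustive search for the optimal and minimax Simon two-stage designs.

    Parameters
    ----------
    p0 : float
        Uninteresting (null) response probability.
    p1 : float
        Target (alternative) response probability; must exceed ``p0``.
    alpha : float
        One-sided type I error bound.
    beta : float
        Type II error bound (power constraint is ``>= 1 - beta``).
    n_max : int
        Largest total sample size enumerated.

    Returns
    -------
    (optimal, minimax) : tuple of SimonDesign
        ``optimal`` minimizes the expected sample size under ``p0`` (ties
        broken by smaller ``n``); ``minimax`` minimizes ``n`` (ties broken by
        smaller expected sample size under ``p0``).

    Raises
    ------
    ValueError
        If ``p1 <= p0``, bounds are outside (0, 1), or no admissible design
        exists within ``n_max`` (message says to increase ``n_max``).
    """
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError("p0 and p1 must lie strictly in (0, 1)")
    if p1 <= p0:
        raise ValueError(f"require p1 > p0, got p0={p0}, p1={p1}")
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie strictly in (0, 1)")
    if n_max < 2:
        raise ValueError("n_max must be at least 2")

    power_min = 1.0 - beta
    best_opt: tuple | None = None  # (en0, n, r1, n1, r)
    best_mini: tuple | None = None  # (n, en0, r1, n1, r)

    for n1 in range(1, n_max):
        x1 = np.arange(n1 + 1)
        pmf0 = binom.pmf(x1, n1, p0)
        pmf1 = binom.pmf(x1, n1, p1)
        cdf0 = np.cumsum(pmf0)  # pet0 as a function of r1
        for n2 in range(1, n_max - n1 + 1):
            n = n1 + n2
            # sf_ext[t + n1] = P(X2 > t); t < 0 -> 1 (stage-2 always clears).
            t = np.arange(-n1, n + 1)
            sf0 = np.where(t < 0, 1.0, binom.sf(np.clip(t, 0, None), n2, p0))
            sf1 = np.where(t < 0, 1.0, binom.sf(np.clip(t, 0, None), n2, p1))
            # Toeplitz index: entry [x1, r] looks up t = r - x1.
            idx = np.arange(n + 1)[None, :] - x1[:, None] + n1
            # cumulative from below: rej[r1, r] = sum_{x1 > r1} pmf[x1]*sf[r-x1]
            c0 = pmf0[:, None] * sf0[idx]
            c1 = pmf1[:, None] * sf1[idx]
            tail0 = np.flip(np.cumsum(np.flip(c0, 0), 0), 0)
            tail1 = np.flip(np.cumsum(np.flip(c1, 0), 0), 0)
            # rows are r1 = 0..n1-1 (r1 = n1 never rejects, excluded)
            alpha_mat = tail0[1:, :]
            power_mat = tail1[1:, :]
            r1_grid = np.arange(n1)[:, None]
            r_grid = np.arange(n + 1)[None, :]
            ok = (alpha_mat <= alpha) & (power_mat >= power_min) & (r_grid >= r1_grid)
            if not ok.any():
                continue
            en0 = n1 + (1.0 - cdf0[:n1]) * n2  # per r1
            adm_r1 = np.where(ok.any(axis=1))[0]
            for r1 in adm_r1:
                r = int(np.argmax(ok[r1]))  # smallest admissible r: max power
                key_opt = (float(en0[r1]), n, int(r1), n1, r)
                key_mini = (n, float(en0[r1]), int(r1), n1, r)
                if best_opt is None or key_opt[:2] < best_opt[:2]:
                    best_opt = key_opt
                if best_mini is None or key_mini[:2] < best_mini[:2]:
                    best_mini = key_mini

    if best_opt is None:
        raise ValueError(
            f"no admissible design with n <= {n_max}; increase n_max"
        )

    en0_o, n_o, r1_o, n1_o, r_o = best_opt
    n_m, en0_m, r1_m, n1_m, r_m = best_mini
    optimal = _evaluate(r1_o, n1_o, r_o, n_o, p0, p1)
    minimax = _evaluate(r1_m, n1_m, r_m, n_m, p0, p1)
    return optimal, minimax
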