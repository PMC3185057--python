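"""Incidence-based richness: sample rarefaction and the Chao2 estimator.

The sampling unit is a dung pile or feeding site; the data are a
binary samples x taxa incidence matrix. Accumulation curves average
the number of distinct taxa in the first t samples over R random
sample orderings (sampling without replacement, 500 randomizations by
default). Total richness is estimated by Chao2 from the uniques Q1
(taxa in exactly one sample) and duplicates Q2 (taxa in exactly two):

    classic          S = S_obs + ((m-1)/m) * Q1^2 / (2 Q2)        (Q2 > 0)
    bias-corrected   S = S_obs + ((m-1)/m) * Q1 (Q1-1) / (2 (Q2+1))

with a 95% confidence interval from the log-normal approximation on
T = S - S_obs (Chao 1987), the convention EstimateS uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

Z95 = 1.96


@dataclass
class RichnessEstimate:
    S_obs: int
    m: int
    Q1: int
    Q2: int
    S_chao2: float
    ci_low: float
    ci_high: float
    variant: str  # "classic" or "bias_corrected"
    se: float = 0.0


@dataclass
class AccumulationCurve:
    """Mean +/- SD accumulated richness for t = 1..m samples."""

    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    R: int
    seed: int | None


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy()
    else:
        X = np.asarray(matrix)
    if X.ndim != 2:
        raise ValueError("incidence matrix must be 2-D (samples x taxa)")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("incidence matrix must be binary 0/1")
    return X.astype(bool)


def rarefy(matrix, R: int = 500, seed: int | None = None) -> AccumulationCurve:
    """Sample-based rarefaction by randomized sample ordering.

    For each t in 1..m, the mean and sample SD (ddof=1) of the number
    of distinct taxa contained in the first t samples, over ``R``
    uniformly random permutations of the sample order. Deterministic
    under a fixed seed.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    X = _as_matrix(matrix)
    m = X.shape[0]
    if m < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    counts = np.empty((R, m), dtype=np.int64)
    for r in range(R):
        perm = rng.permutation(m)
        seen = np.maximum.accumulate(X[perm], axis=0)
        counts[r] = seen.sum(axis=1)
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if R > 1 else np.zeros(m)
    return AccumulationCurve(t=np.arange(1, m + 1), mean=mean, sd=sd, R=R, seed=seed)


def expected_rarefaction(matrix) -> np.ndarray:
    """Closed-form expected accumulation (Mao Tau).

    E[S(t)] = S_obs - sum_i C(m - m_i, t) / C(m, t), where m_i is the
    number of samples containing taxon i. Exact expectation of the
    randomized curve; used as an independent check on :func:`rarefy`.
    """
    from scipy.special import gammaln

    X = _as_matrix(matrix)
    m = X.shape[0]
    mi = X.sum(axis=0)
    mi = mi[mi > 0]
    S_obs = mi.size

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(m)
    for t in range(1, m + 1):
        absent = np.zeros(mi.size)
        ok = (m - mi) >= t
        absent[ok] = np.exp(log_choose(m - mi[ok], t) - log_choose(m, t))
        out[t - 1] = S_obs - absent.sum()
    return out


def chao2(matrix, variant: str = "auto", small_sample_correction: bool = True) -> RichnessEstimate:
    """Chao2 total-richness estimate with 95% log-normal CI.

    ``variant`` is "classic", "bias_corrected", or "auto" (classic
    when Q2 > 0, bias-corrected when Q2 = 0 — the EstimateS 8.2
    convention). ``small_sample_correction`` applies the (m-1)/m
    factor.
    """
    X = _as_matrix(matrix)
    m = X.shape[0]
    mi = X.sum(axis=0)
    S_obs = int((mi > 0).sum())
    Q1 = int((mi == 1).sum())
    Q2 = int((mi == 2).sum())
    if S_obs == 0:
        return RichnessEstimate(0, m, 0, 0, 0.0, 0.0, 0.0, "classic", 0.0)
    A = (m - 1) / m if small_sample_correction else 1.0

    if variant == "auto":
        variant = "classic" if Q2 > 0 else "bias_corrected"
    if variant == "classic":
        if Q2 == 0:
            raise ValueError("classic Chao2 undefined with Q2=0; use bias_corrected")
        T = A * Q1 * Q1 / (2 * Q2)
        r = Q1 / Q2
        var = Q2 * (0.5 * A * r**2 + A**2 * r**3 + 0.25 * A**2 * r**4)
    elif variant == "bias_corrected":
        T = A * Q1 * (Q1 - 1) / (2 * (Q2 + 1))
        var = (
            A * Q1 * (Q1 - 1) / (2 * (Q2 + 1))
            + A**2 * Q1 * (2 * Q1 - 1) ** 2 / (4 * (Q2 + 1) ** 2)
            + A**2 * Q1**2 * Q2 * (Q1 - 1) ** 2 / (4 * (Q2 + 1) ** 4)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    S = S_obs + T

    if T > 0 and var > 0:
        K = np.exp(Z95 * np.sqrt(np.log(1 + var / T**2)))
        ci_low = S_obs + T / K
        ci_high = S_obs + T * K
    else:
        ci_low = ci_high = float(S)
    return RichnessEstimate(
        S_obs, m, Q1, Q2, float(S), float(ci_low), float(ci_high), variant,
        float(np.sqrt(max(var, 0.0))),
    )


class Chao2Richness(BaseEstimator):
    """Chao2 estimator with a scikit-learn surface.

    Parameters
    ----------
    variant : {"auto", "classic", "bias_corrected"}
    small_sample_correction : bool
        Include the (m-1)/m factor.

    Attributes
    ----------
    S_obs_, Q1_, Q2_, m_ : int
    S_chao2_, ci_low_, ci_high_ : float
    estimate_ : RichnessEstimate
    """

    def __init__(self, variant: str = "auto", small_sample_correction: bool = True):
        self.variant = variant
        self.small_sample_correction = small_sample_correction

    def fit(self, X, y=None):
        est = chao2(X, variant=self.variant, small_sample_correction=self.small_sample_correction)
        self.estimate_ = est
        self.S_obs_, self.Q1_, self.Q2_, self.m_ = est.S_obs, est.Q1, est.Q2, est.m
        self.S_chao2_, self.ci_low_, self.ci_high_ = est.S_chao2, est.ci_low, est.ci_high
        return self


class SampleRarefaction(BaseEstimator):
    """Randomized sample-based rarefaction with a scikit-learn surface.

    Parameters
    ----------
    R : int
        Number of random sample orderings (default 500).
    seed : int or None

    Attributes
    ----------
    t_, mean_, sd_ : ndarray
    curve_ : AccumulationCurve
    """

    def __init__(self, R: int = 500, seed: int | None = None):
        self.R = R
        self.seed = seed

    def fit(self, X, y=None):
        curve = rarefy(X, R=self.R, seed=self.seed)
        self.curve_ = curve
        self.t_, self.mean_, self.sd_ = curve.t, curve.mean, curve.sd
        return self
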