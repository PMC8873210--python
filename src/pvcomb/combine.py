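"""Combination tests for a vector of p-values.

Implements the Cauchy combination test (CCT), the minimum-p test (MinP,
Šidák or Bonferroni calibrated), the two-stage robust tests MCM
(MinP-CCT-MinP) and CMC (CCT-MinP-CCT), and the classical Fisher and
Stouffer (z-test) combiners for independent p-values.

The CCT transforms each p-value to the standard-Cauchy scale,
``T_i = tan[(0.5 - P_i) * pi]``, and combines them as a convex combination
``T = sum_i w_i T_i``.  Under each individual null, ``T_i`` is standard
Cauchy; under independence so is ``T``, and the combined p-value
``P[C(0,1) >= T]`` is exactly uniform.  Its heavy tail also makes the
Cauchy approximation accurate at small significance levels under arbitrary
dependence.  The combined p-value always lies between the smallest and
largest input p-value, so the CCT can never beat its own best input --
the reason the two-stage MCM/CMC hybrids with MinP exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

__all__ = [
    "PValueVector",
    "CombinedResult",
    "cauchy_transform",
    "cct_pvalue",
    "minp_pvalue",
    "mcm_pvalue",
    "cmc_pvalue",
    "fisher_pvalue",
    "stouffer_pvalue",
    "combine_all",
]

#: p-values of exactly 1 are clipped to this before the Cauchy transform
#: (tan((0.5-1)*pi) = -inf); the limit convention keeps results finite.
P_ONE_CLIP = 1.0 - 1e-15

_MINP_MODES = ("sidak", "bonferroni")


@dataclass(frozen=True)
class PValueVector:
    """An ordered collection of p-values with optional non-negative weights.

    Parameters
    ----------
    values
        p-values, each in (0, 1].
    weights
        Optional non-negative weights, same length as ``values``, at least
        one strictly positive.  Normalized to sum to one on access.
    """

    values: np.ndarray
    weights: np.ndarray | None = None

    def __init__(self, values, weights=None):
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if values.ndim != 1 or values.size < 1:
            raise ValueError("p-value vector must be one-dimensional and non-empty")
        bad = (values <= 0.0) | (values > 1.0) | ~np.isfinite(values)
        if bad.any():
            raise ValueError(
                f"p-value out of (0,1]: {float(values[bad][0])!r} "
                f"at index {int(np.flatnonzero(bad)[0])}"
            )
        if weights is not None:
            weights = np.atleast_1d(np.asarray(weights, dtype=float))
            if weights.shape != values.shape:
                raise ValueError(
                    f"weights length {weights.size} does not match values length {values.size}"
                )
            if (weights < 0).any() or ~np.isfinite(weights).all():
                raise ValueError("weights must be finite and non-negative")
            if not (weights > 0).any():
                raise ValueError("weights must not be all zero")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return self.values.size

    def normalized_weights(self) -> np.ndarray:
        """Weights scaled to sum to one (equal weights when none supplied)."""
        if self.weights is None:
            return np.full(self.k, 1.0 / self.k)
        return self.weights / self.weights.sum()


@dataclass(frozen=True)
class CombinedResult:
    """Outcome of one combination test.

    ``statistic`` is the test statistic where the method defines one
    (the Cauchy-scale sum for CCT/CMC, min p for MinP, chi-square for
    Fisher, z for Stouffer) and None for MCM, which is a Bonferroni
    combination without a statistic of its own.
    """

    method: str
    statistic: float | None
    pvalue: float
    k: int
    minp_mode: str | None = None
    weights_normalized: tuple[float, ...] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "k": self.k,
            "minp_mode": self.minp_mode,
            "weights_normalized": list(self.weights_normalized)
            if self.weights_normalized is not None
            else None,
        }


def _as_pvector(pv, weights=None) -> PValueVector:
    if isinstance(pv, PValueVector):
        if weights is not None:
            raise ValueError("weights given both inside and alongside a PValueVector")
        return pv
    return PValueVector(pv, weights)


def cauchy_transform(p):
    """Map p-values to the standard-Cauchy scale, tan[(0.5 - p) * pi].

    Evaluated through the exactly equivalent reflection ``cot(p*pi)`` for
    p < 1/2 and ``-cot((1-p)*pi)`` for p > 1/2, which keeps the relative
    error at a few ulp over the whole open interval -- the direct tangent
    form loses accuracy near its pole.  Strictly decreasing in p, and
    antisymmetric: the transforms of p and 1-p are exact negatives.

    Accepts scalars or arrays; every element must lie strictly in (0, 1).
    """
    arr = np.asarray(p, dtype=float)
    if ((arr <= 0.0) | (arr >= 1.0) | ~np.isfinite(arr)).any():
        off = arr[((arr <= 0.0) | (arr >= 1.0) | ~np.isfinite(arr))].flat[0]
        raise ValueError(f"cauchy_transform requires p in (0,1); got {off!r}")
    out = np.empty_like(arr)
    lo = arr < 0.5
    hi = arr > 0.5
    out[lo] = 1.0 / np.tan(arr[lo] * np.pi)
    out[hi] = -1.0 / np.tan((1.0 - arr[hi]) * np.pi)
    out[~lo & ~hi] = 0.0
    return out if out.ndim else float(out)


def _cauchy_sf(t):
    """Upper-tail standard-Cauchy probability, accurate in both tails.

    arctan2(1, t)/pi == 0.5 - arctan(t)/pi, but evaluates the small
    upper tail as arctan(1/t)/pi ~ 1/(pi*t) without cancellation.
    """
    return np.arctan2(1.0, t) / np.pi


def _cct_stat_rows(P: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Row-wise CCT statistic for a 2-D array of p-values in (0, 1]."""
    T = cauchy_transform(np.minimum(P, P_ONE_CLIP))
    if w is None:
        return T.mean(axis=-1)
    return T @ w


def cct_pvalue(pv, weights=None) -> CombinedResult:
    """Cauchy combination test.

    The statistic is ``sum_i w_i tan[(0.5 - P_i) pi]`` with weights
    normalized to sum to one (equal by default); the p-value is the
    upper-tail standard-Cauchy probability of the statistic.  By
    construction the result lies in [min P_i, max P_i].  Inputs equal to
    1 are clipped to ``1 - 1e-15`` before transforming.
    """
    pv = _as_pvector(pv, weights)
    w = pv.normalized_weights()
    stat = float(_cct_stat_rows(pv.values[None, :], w)[0])
    return CombinedResult(
        method="CCT",
        statistic=stat,
        pvalue=float(_cauchy_sf(stat)),
        k=pv.k,
        weights_normalized=tuple(float(x) for x in w),
    )


def _minp_rows(pmin: np.ndarray, k: int, mode: str) -> np.ndarray:
    if mode == "sidak":
        return -np.expm1(k * np.log1p(-pmin))
    if mode == "bonferroni":
        return np.minimum(1.0, k * pmin)
    raise ValueError(f"unknown MinP mode {mode!r}; expected one of {_MINP_MODES}")


def minp_pvalue(pv, mode: str = "sidak") -> CombinedResult:
    """Minimum-p global test.

    ``sidak`` calibrates the smallest p-value as 1 - (1 - min P)^k (exact
    under independence); ``bonferroni`` as min(1, k * min P) (valid under
    arbitrary dependence).  Weights are ignored.
    """
    pv = _as_pvector(pv)
    pmin = float(pv.values.min())
    p = float(_minp_rows(np.asarray(pmin), pv.k, mode))
    return CombinedResult(method="MinP", statistic=pmin, pvalue=p, k=pv.k, minp_mode=mode)


def mcm_pvalue(pv, minp_mode: str = "bonferroni") -> CombinedResult:
    """MinP-CCT-MinP: a Bonferroni combination of CCT and MinP.

    Applies CCT and MinP to the same p-values and returns
    ``2 * min{p_CCT, p_MinP, 0.5}``, which always lies in (0, 1].
    """
    pv = _as_pvector(pv)
    p_cct = cct_pvalue(pv).pvalue
    p_minp = minp_pvalue(pv, mode=minp_mode).pvalue
    p = 2.0 * min(p_cct, p_minp, 0.5)
    return CombinedResult(method="MCM", statistic=None, pvalue=p, k=pv.k, minp_mode=minp_mode)


def cmc_pvalue(pv, minp_mode: str = "bonferroni") -> CombinedResult:
    """CCT-MinP-CCT: a second-stage CCT over the pair {p_CCT, p_MinP}.

    The two first-stage p-values are combined with an equal-weight CCT;
    a first-stage value of exactly 1 is clipped before the second
    transform (limit convention).
    """
    pv = _as_pvector(pv)
    p_cct = cct_pvalue(pv).pvalue
    p_minp = minp_pvalue(pv, mode=minp_mode).pvalue
    inner = PValueVector([p_cct, p_minp])
    res = cct_pvalue(inner)
    return CombinedResult(
        method="CMC", statistic=res.statistic, pvalue=res.pvalue, k=pv.k, minp_mode=minp_mode
    )


def fisher_pvalue(pv) -> CombinedResult:
    """Fisher's chi-square combination for independent p-values.

    ``X^2 = -2 sum_i ln P_i`` against chi-square with 2k degrees of
    freedom.
    """
    pv = _as_pvector(pv)
    stat = float(-2.0 * np.log(pv.values).sum())
    return CombinedResult(
        method="Fisher", statistic=stat, pvalue=float(chi2.sf(stat, 2 * pv.k)), k=pv.k
    )


def stouffer_pvalue(pv) -> CombinedResult:
    """Stouffer's z-test combination for independent p-values.

    ``Z = sum_i Phi^{-1}(1 - P_i) / sqrt(k)``, combined p-value
    ``1 - Phi(Z)``.  The quantile is computed as ``-Phi^{-1}(P_i)``, which
    is accurate for small p where ``1 - P_i`` would round to 1.  Values of
    exactly 1 are rejected (infinite quantile).
    """
    pv = _as_pvector(pv)
    if (pv.values >= 1.0).any():
        raise ValueError("stouffer_pvalue requires p in (0,1); got a value of 1")
    z = float(-ndtri(pv.values).sum() / math.sqrt(pv.k))
    return CombinedResult(method="StoufferZ", statistic=z, pvalue=float(ndtr(-z)), k=pv.k)


def combine_all(pv, minp_mode: str = "sidak", weights=None) -> list[CombinedResult]:
    """Run every combiner on the same input; MCM/CMC reuse ``minp_mode``."""
    pv = _as_pvector(pv, weights)
    return [
        cct_pvalue(pv),
        minp_pvalue(pv, mode=minp_mode),
        mcm_pvalue(pv, minp_mode=minp_mode),
        cmc_pvalue(pv, minp_mode=minp_mode),
        fisher_pvalue(pv),
        stouffer_pvalue(pv),
    ]
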