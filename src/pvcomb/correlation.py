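"""Structured correlation matrices for the Monte-Carlo experiments.

Three families of k x k correlation matrices for the z-score vector:

* ``expo`` -- AR(1) exponential decay, sigma_ij = rho^|i-j|, rho in [0, 1).
* ``poly`` -- polynomial decay, sigma_ij = 1 / (0.7 + |i-j|^r), r > 0,
  unit diagonal.
* ``sig``  -- a singular (rank k/5) matrix: A is the k/5 x k matrix with
  a_ij = d^|i-j|, and Sigma is A^T A rescaled to unit diagonal.

The singular family deliberately produces perfectly linearly dependent
coordinates, so sampling factorizations go through a symmetric
eigendecomposition with small-eigenvalue clipping rather than Cholesky.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationSpec",
    "expo_sigma",
    "poly_sigma",
    "sig_sigma",
    "validate_correlation",
    "factorize_for_sampling",
]

_MODELS = ("expo", "poly", "sig")

#: eigenvalues below -RTOL * lambda_max fail validation; those in
#: [-RTOL * lambda_max, 0) are treated as numerically zero.
EIG_RTOL = 1e-8


@dataclass(frozen=True)
class CorrelationSpec:
    """One correlation model with its parameter.

    ``parameter`` is rho for ``expo`` (in [0, 1)), r for ``poly`` (> 0),
    and d for ``sig`` (in (0, 1), k divisible by 5).
    """

    model: str
    k: int
    parameter: float

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"unknown correlation model {self.model!r}; expected one of {_MODELS}")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.model == "sig" and self.k % 5 != 0:
            raise ValueError(
                f"the singular model requires k divisible by 5 (A is a k/5 x k matrix); got k={self.k}"
            )

    def matrix(self) -> np.ndarray:
        if self.model == "expo":
            return expo_sigma(self.k, self.parameter)
        if self.model == "poly":
            return poly_sigma(self.k, self.parameter)
        return sig_sigma(self.k, self.parameter)

    def to_dict(self) -> dict:
        return {"model": self.model, "k": self.k, "parameter": self.parameter}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationSpec":
        return cls(model=d["model"], k=int(d["k"]), parameter=float(d["parameter"]))


def _distance(k: int) -> np.ndarray:
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :])


def expo_sigma(k: int, rho: float) -> np.ndarray:
    """AR(1) correlation: sigma_ij = rho^|i-j|; positive definite for rho < 1."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"expo model requires rho in [0, 1); got {rho}")
    if k < 1:
        raise ValueError("k must be a positive integer")
    return rho ** _distance(k)


def poly_sigma(k: int, r: float) -> np.ndarray:
    """Polynomial decay: unit diagonal, sigma_ij = 1/(0.7 + |i-j|^r) off it.

    Not positive definite for every (k, r); eigenvalues are checked and a
    failure is raised loudly rather than repaired.
    """
    if not r > 0:
        raise ValueError(f"poly model requires r > 0; got {r}")
    if k < 1:
        raise ValueError("k must be a positive integer")
    dist = _distance(k)
    with np.errstate(divide="ignore"):
        sigma = 1.0 / (0.7 + dist.astype(float) ** r)
    np.fill_diagonal(sigma, 1.0)
    validate_correlation(sigma, allow_singular=False)
    return sigma


def sig_sigma(k: int, d: float) -> np.ndarray:
    """Singular model: Sigma = D^T A^T A D with A the k/5 x k decay matrix.

    a_ij = d^|i-j| for row i in 1..k/5 and column j in 1..k; D is the
    diagonal normalizer (diag of A^T A)^(-1/2), so Sigma has unit diagonal
    and rank exactly k/5.  For k = 5 the single row of A makes Sigma the
    all-ones matrix.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"sig model requires d in (0, 1); got {d}")
    if k % 5 != 0 or k < 5:
        raise ValueError(
            f"the singular model requires k divisible by 5 (A is a k/5 x k matrix); got k={k}"
        )
    m = k // 5
    i = np.arange(m)[:, None]
    j = np.arange(k)[None, :]
    A = d ** np.abs(i - j)
    ata = A.T @ A
    dnorm = 1.0 / np.sqrt(np.diag(ata))
    return dnorm[:, None] * ata * dnorm[None, :]


def validate_correlation(sigma: np.ndarray, allow_singular: bool = True) -> None:
    """Check symmetry, unit diagonal, and positive semidefiniteness.

    Raises ValueError on failure.  With ``allow_singular=False`` the
    smallest eigenvalue must also be strictly positive.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-12, rtol=0.0):
        raise ValueError("correlation matrix is not symmetric within 1e-12")
    if not np.allclose(np.diag(sigma), 1.0, atol=1e-12, rtol=0.0):
        raise ValueError("correlation matrix does not have a unit diagonal within 1e-12")
    w = np.linalg.eigvalsh(sigma)
    lam_max = float(w[-1])
    if w[0] < -EIG_RTOL * lam_max:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {w[0]:.3e})"
        )
    if not allow_singular and w[0] <= EIG_RTOL * lam_max:
        raise ValueError(
            f"correlation matrix is numerically singular (min eigenvalue {w[0]:.3e})"
        )


def factorize_for_sampling(sigma: np.ndarray) -> np.ndarray:
    """Return B with B^T B = Sigma, for generating MVN(0, Sigma) draws.

    Uses a symmetric eigendecomposition so singular matrices (the ``sig``
    model) are handled by the same code path as positive-definite ones:
    eigenvalues in [-1e-8 * lambda_max, 0) are clipped to zero, anything
    more negative is an error.  Draw Z with i.i.d. standard-normal entries
    and form ``Z @ B`` to get rows with covariance Sigma.
    """
    sigma = np.asarray(sigma, dtype=float)
    validate_correlation(sigma, allow_singular=True)
    w, V = np.linalg.eigh(sigma)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)).T
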