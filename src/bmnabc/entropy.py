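"""Sample entropy and multiscale entropy.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative log of the conditional probability that two sequences that match for
``m`` points (within a tolerance ``r``, Chebyshev distance) also match for
``m + 1`` points.  Self-matches are excluded.  Multiscale entropy (MSE)
repeats the computation on coarse-grained (block-averaged) copies of the
series, exposing complexity at progressively slower time scales.

Conventions used here, stated once:

* the tolerance is relative: matches are accepted at Chebyshev distance
  ``<= r * SD(x)`` so that SampEn is invariant to amplitude rescaling;
* template counts use the first ``N - m`` templates for both lengths ``m``
  and ``m + 1`` so the two counts range over the same index set;
* a series with no ``m + 1``-matches (A = 0) returns ``+inf`` as a sentinel
  rather than raising;
* by default the tolerance is recomputed from the SD of each coarse-grained
  series (each scale is its own SampEn problem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "SampEnParams",
    "MSEParams",
    "sampen_counts",
    "sample_entropy",
    "coarse_grain",
    "multiscale_entropy",
]


@dataclass(frozen=True)
class SampEnParams:
    """Template length ``m`` and SD-relative tolerance ``r``."""

    m: int = 2
    r: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance fraction r must be > 0, got {self.r}")


@dataclass(frozen=True)
class MSEParams:
    """Maximum coarse-graining scale and the minimum usable series length."""

    max_tau: int = 20
    min_points: int = 150

    def __post_init__(self) -> None:
        if self.max_tau < 1:
            raise ValueError(f"max_tau must be >= 1, got {self.max_tau}")
        if self.min_points < 2:
            raise ValueError(f"min_points must be >= 2, got {self.min_points}")


@njit(cache=True)
def _count_templates(x, m, tol):  # pragma: no cover - exercised via wrapper
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > tol:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    return a, b


def sampen_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Return raw (A, B) template-match counts at absolute tolerance ``tol``.

    A counts matching pairs of length ``m + 1``, B of length ``m``, over
    unordered index pairs, self-matches excluded.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if x.shape[0] < m + 2:
        raise ValueError(
            f"series of length {x.shape[0]} too short for m={m} (need >= {m + 2})"
        )
    a, b = _count_templates(x, m, tol)
    return int(a), int(b)


def sample_entropy(x: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn(m, r, N) = -log(A / B) with tolerance ``r * SD(x)``.

    Returns 0.0 for a constant series (every template matches every other at
    both lengths) and ``+inf`` when no m+1-length matches exist.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = float(np.std(x))
    a, b = sampen_counts(x, params.m, params.r * sd)
    if b == 0 or a == 0:
        return math.inf
    return -math.log(a / b)


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Block-average ``x`` into non-overlapping windows of length ``tau``.

    Output length is ``floor(N / tau)``; trailing samples that do not fill a
    window are dropped.  ``tau = 1`` is the identity.
    """
    x = np.asarray(x, dtype=np.float64)
    if tau < 1:
        raise ValueError(f"scale tau must be >= 1, got {tau}")
    n = x.shape[0]
    if tau > n:
        raise ValueError(f"scale tau={tau} exceeds series length {n}")
    if tau == 1:
        return x.copy()
    k = n // tau
    return x[: k * tau].reshape(k, tau).mean(axis=1)


def multiscale_entropy(
    x: np.ndarray,
    sampen: SampEnParams = SampEnParams(),
    mse: MSEParams = MSEParams(),
    recompute_r: bool = True,
) -> np.ndarray:
    """SampEn of the coarse-grained series at scales ``1 .. max_tau``.

    With ``recompute_r`` (default) the tolerance at each scale is
    ``r * SD`` of that scale's coarse-grained series; otherwise the scale-1
    absolute tolerance is reused everywhere.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    feasible = n // mse.min_points
    if n // mse.max_tau < mse.min_points:
        raise ValueError(
            f"series of length {n} supports at most scale tau={max(feasible, 0)} "
            f"with min_points={mse.min_points}; requested max_tau={mse.max_tau}"
        )
    tol1 = sampen.r * float(np.std(x))
    out = np.empty(mse.max_tau, dtype=np.float64)
    for tau in range(1, mse.max_tau + 1):
        cg = coarse_grain(x, tau)
        tol = sampen.r * float(np.std(cg)) if recompute_r else tol1
        a, b = sampen_counts(cg, sampen.m, tol)
        out[tau - 1] = math.inf if (a == 0 or b == 0) else -math.log(a / b)
    return out
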