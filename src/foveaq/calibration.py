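"""Quantile-based calibration of latent quotient distributions.

The study groups are summarised in the source cohort only by a median and
interquartile range of each temporal/nasal thickness quotient, plus the
per-group classification rates observed at a fixed diagnostic cut-off.  This
module turns those printed summaries into samplable one-dimensional
distributions:

* :func:`fit_quantile_normal` — the minimal two-parameter fit: a normal whose
  median and IQR match the targets.
* :func:`fit_truncated_quantiles` / :func:`calibrate_truncated` — a truncated
  normal whose *post-truncation* quantiles match the targets (root-finding on
  the truncated quantile function).
* :class:`QuotientModel` — an ordered mixture of components (truncated-normal
  bulk plus optional uniform "contamination" bands adjacent to a cut-off)
  with an exact piecewise inverse CDF, used by the cohort generator.

All quantities here are dimensionless thickness quotients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationError",
    "fit_quantile_normal",
    "fit_truncated_quantiles",
    "calibrate_truncated",
    "NormalComponent",
    "TruncatedNormalComponent",
    "UniformComponent",
    "QuotientModel",
]

#: half-width of the central 50% of a standard normal (2 * Phi^-1(0.75))
NORMAL_IQR = 2.0 * stats.norm.ppf(0.75)


class CalibrationError(ValueError):
    """Raised when quantile targets are inconsistent or cannot be matched.

    Carries the achieved-minus-target residuals (when a fit was attempted)
    in :attr:`residuals`.
    """

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


def _check_order(median: float, q1: float, q3: float, label: str = "") -> None:
    if not (q1 <= median <= q3):
        where = f" for {label}" if label else ""
        raise CalibrationError(
            f"quantile ordering violated{where}: require q1 <= median <= q3, "
            f"got q1={q1}, median={median}, q3={q3}"
        )


def fit_quantile_normal(
    median: float, q1: float, q3: float, label: str = ""
) -> tuple[float, float]:
    """Normal distribution matching a median and interquartile range.

    Returns ``(mu, sigma)`` with ``mu = median`` and
    ``sigma = (q3 - q1) / (2 * Phi^-1(0.75)) ~= (q3 - q1) / 1.349``.
    A degenerate IQR (``q1 == q3``) yields ``sigma = 0``.
    """
    _check_order(median, q1, q3, label)
    return float(median), float((q3 - q1) / NORMAL_IQR)


def fit_truncated_quantiles(
    targets: Sequence[float],
    probs: Sequence[float],
    bounds: tuple[float, float],
    sigma_bracket: tuple[float, float] = (1e-4, 5.0),
) -> tuple[float, float, np.ndarray]:
    """Fit (mu, sigma) of a normal truncated to ``bounds`` to three quantiles.

    The middle target (usually the median) is matched exactly; the two outer
    targets are matched in least squares.  ``probs`` are the post-truncation
    probability levels of the three targets.  Returns
    ``(mu, sigma, residuals)`` where residuals are achieved-minus-target for
    each of the three quantiles.

    With two parameters against three constraints an exact fit generally does
    not exist; callers decide what residual is acceptable.
    """
    q1, med, q3 = (float(v) for v in targets)
    p1, p2, p3 = (float(p) for p in probs)
    lo, hi = bounds
    if not (lo < hi):
        raise CalibrationError(f"empty truncation interval ({lo}, {hi})")
    if not (lo <= q1 and q3 <= hi):
        raise CalibrationError(
            f"truncation interval ({lo}, {hi}) does not contain quartiles "
            f"[{q1}, {q3}]"
        )
    if q1 == q3:
        return med, 0.0, np.zeros(3)

    scale0 = max(q3 - q1, 1e-6)

    def mu_for_sigma(sig: float) -> float:
        def f(mu: float) -> float:
            a, b = (lo - mu) / sig, (hi - mu) / sig
            return stats.truncnorm.ppf(p2, a, b, loc=mu, scale=sig) - med

        span = 60.0 * sig + 10.0 * scale0
        return optimize.brentq(f, med - span, med + span, xtol=1e-12)

    def outer_loss(log_sig: float) -> float:
        sig = float(np.exp(log_sig))
        try:
            mu = mu_for_sigma(sig)
        except ValueError:
            return 1e9
        a, b = (lo - mu) / sig, (hi - mu) / sig
        r1 = stats.truncnorm.ppf(p1, a, b, loc=mu, scale=sig) - q1
        r3 = stats.truncnorm.ppf(p3, a, b, loc=mu, scale=sig) - q3
        return r1 * r1 + r3 * r3

    res = optimize.minimize_scalar(
        outer_loss,
        bounds=(np.log(sigma_bracket[0] * scale0), np.log(sigma_bracket[1] / max(scale0, 1e-3))),
        method="bounded",
        options={"xatol": 1e-11},
    )
    sigma = float(np.exp(res.x))
    mu = mu_for_sigma(sigma)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    achieved = stats.truncnorm.ppf([p1, p2, p3], a, b, loc=mu, scale=sigma)
    return float(mu), sigma, achieved - np.array([q1, med, q3])


def calibrate_truncated(
    median: float,
    q1: float,
    q3: float,
    bounds: tuple[float, float] = (-np.inf, np.inf),
    tol: float = 1e-4,
    label: str = "",
) -> tuple[float, float]:
    """Truncated normal whose post-truncation quartiles match the targets.

    With infinite bounds this reduces exactly to :func:`fit_quantile_normal`.
    If no truncated normal can reproduce the target quantiles to ``tol``
    (the quantile spacing may demand a skew the family cannot produce under
    the given bounds), a :class:`CalibrationError` carrying the best-fit
    residuals is raised.
    """
    _check_order(median, q1, q3, label)
    lo, hi = bounds
    if np.isneginf(lo) and np.isposinf(hi):
        return fit_quantile_normal(median, q1, q3, label)
    mu, sigma, resid = fit_truncated_quantiles(
        (q1, median, q3), (0.25, 0.5, 0.75), (lo, hi)
    )
    if np.max(np.abs(resid)) > tol:
        raise CalibrationError(
            f"truncated-normal calibration did not converge to tol={tol}"
            + (f" for {label}" if label else "")
            + f"; best residuals (q1, median, q3) = {np.round(resid, 6).tolist()}",
            residuals=resid,
        )
    return mu, sigma


# ---------------------------------------------------------------------------
# mixture components


@dataclass(frozen=True)
class NormalComponent:
    mu: float
    sigma: float

    support: tuple[float, float] = (-np.inf, np.inf)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.full_like(np.asarray(u, dtype=float), self.mu)
        return stats.norm.ppf(u, loc=self.mu, scale=self.sigma)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return (np.asarray(x, dtype=float) >= self.mu).astype(float)
        return stats.norm.cdf(x, loc=self.mu, scale=self.sigma)

    def mean(self) -> float:
        return self.mu


@dataclass(frozen=True)
class TruncatedNormalComponent:
    mu: float
    sigma: float
    lower: float
    upper: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.mu) / self.sigma, (self.upper - self.mu) / self.sigma

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.cdf(x, a, b, loc=self.mu, scale=self.sigma)

    def mean(self) -> float:
        a, b = self._ab()
        return float(stats.truncnorm.mean(a, b, loc=self.mu, scale=self.sigma))


@dataclass(frozen=True)
class UniformComponent:
    lower: float
    upper: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.lower, self.upper)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return np.clip(
            (np.asarray(x, dtype=float) - self.lower) / (self.upper - self.lower), 0.0, 1.0
        )

    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class QuotientModel:
    """Support-ordered mixture with an exact piecewise inverse CDF.

    Components must be ordered so that the support of component *i* lies
    entirely below the support of component *i+1*; the piecewise quantile
    function is then the true inverse CDF of the mixture, which lets the
    cohort generator drive all quotient kinds from a single shared uniform
    per patient (comonotone coupling).
    """

    components: tuple
    weights: tuple
    label: str = ""
    fit_residuals: tuple = field(default=(), compare=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise CalibrationError(f"mixture weights must be a distribution, got {self.weights}")
        uppers = [c.support[1] for c in self.components[:-1]]
        lowers = [c.support[0] for c in self.components[1:]]
        if any(u > l + 1e-12 for u, l in zip(uppers, lowers)):
            raise CalibrationError("mixture components must have ordered, disjoint supports")

    def ppf(self, u) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.empty_like(u)
        edges = np.concatenate([[0.0], np.cumsum(self.weights)])
        edges[-1] = 1.0
        for i, comp in enumerate(self.components):
            lo, hi = edges[i], edges[i + 1]
            m = (u >= lo) & (u < hi) if i < len(self.components) - 1 else (u >= lo) & (u <= hi)
            if np.any(m):
                out[m] = comp.ppf((u[m] - lo) / (hi - lo))
        return out

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros_like(x)
        for w, comp in zip(self.weights, self.components):
            out += w * comp.cdf(x)
        return out

    def mean(self) -> float:
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))

    def median(self) -> float:
        return float(self.ppf(0.5)[0])

    def quartiles(self) -> tuple[float, float, float]:
        q = self.ppf([0.25, 0.5, 0.75])
        return float(q[0]), float(q[1]), float(q[2])

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.ppf(rng.random(size))
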