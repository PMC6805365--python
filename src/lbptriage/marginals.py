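"""Moment-matched marginals for bounded questionnaire scales.

Questionnaire totals live on closed, discretized ranges (RMDQ 0-24 in
integer steps, EQ-5D index 0-1 in 0.001 steps, ...), yet cohort tables
summarize them by mean and SD.  A plain normal truncated to the range
cannot always realize a printed (mean, SD) pair — reference-group pain
scales are strongly overdispersed relative to their mean — so the
generator uses a *censored-and-rounded* normal: draw X ~ N(mu, sigma),
clip to the instrument range, round to the instrument granularity.  The
point masses the censoring creates at the scale ends (e.g. the many zeros
of a pain-free group) are exactly what such data look like.

``solve_censored_normal`` inverts the family numerically: given a target
mean and SD *of the discretized law*, it finds (mu, sigma) whose
censored-rounded moments match, so configured summary statistics are
recovered in expectation by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = ["ScaleMarginal", "solve_censored_normal"]


@dataclass(frozen=True)
class ScaleMarginal:
    """A censored-rounded normal marginal on [lo, hi] with step ``gran``."""

    mu: float
    sigma: float
    lo: float
    hi: float
    gran: float
    sign: int = 1  # -1 couples the scale inversely to severity

    def sample(self, gauss: np.ndarray) -> np.ndarray:
        """Transform standard-normal draws into scale values."""
        x = self.mu + self.sigma * (self.sign * gauss)
        x = np.clip(x, self.lo, self.hi)
        steps = np.round((x - self.lo) / self.gran)
        return self.lo + steps * self.gran


def _discrete_moments(
    mu: float, sigma: float, lo: float, hi: float, gran: float
) -> tuple[float, float]:
    """Mean and SD of round(clip(N(mu, sigma), lo, hi)) to the grid."""
    values = np.arange(lo, hi + gran / 2, gran)
    upper_edges = values + gran / 2
    cdf = norm.cdf(upper_edges, loc=mu, scale=sigma)
    cdf[-1] = 1.0  # top bin absorbs the upper tail
    probs = np.diff(np.concatenate(([0.0], cdf)))
    mean = float(np.dot(probs, values))
    var = float(np.dot(probs, (values - mean) ** 2))
    return mean, float(np.sqrt(var))


def solve_censored_normal(
    target_mean: float,
    target_sd: float,
    lo: float,
    hi: float,
    gran: float,
    sign: int = 1,
    tol: float = 1e-6,
) -> ScaleMarginal:
    """Find (mu, sigma) whose censored-rounded moments hit the targets.

    Raises ``ValueError`` when the targets are unattainable on the scale
    (e.g. SD larger than the scale can carry at that mean).
    """
    if not (lo <= target_mean <= hi):
        raise ValueError(f"target mean {target_mean} outside scale [{lo}, {hi}]")
    if target_sd < 0:
        raise ValueError("target SD must be non-negative")
    if target_sd == 0:
        snapped = lo + round((target_mean - lo) / gran) * gran
        if abs(snapped - target_mean) > 1e-9:
            raise ValueError("zero-SD target mean must sit on the scale grid")
        return ScaleMarginal(target_mean, 0.0, lo, hi, gran, sign)

    def residual(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        m, s = _discrete_moments(mu, float(np.exp(log_sigma)), lo, hi, gran)
        return np.array([m - target_mean, s - target_sd])

    width = hi - lo
    starts = [
        (target_mean, target_sd),
        (target_mean, 2 * target_sd),
        (target_mean - target_sd, 2 * target_sd),
        (target_mean - 2 * target_sd, 4 * target_sd),
        (lo - width / 2, width),
        (lo - width, 1.5 * width),
        (hi + width / 2, width),
    ]
    best = None
    for mu0, sd0 in starts:
        sol = optimize.root(
            residual, np.array([mu0, np.log(max(sd0, gran))]), method="hybr"
        )
        err = float(np.max(np.abs(residual(sol.x))))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < tol:
            break
    err, x = best
    if err >= tol:
        raise ValueError(
            f"no censored-normal marginal reaches mean {target_mean}, "
            f"SD {target_sd} on [{lo}, {hi}] (residual {err:.2e})"
        )
    return ScaleMarginal(float(x[0]), float(np.exp(x[1])), lo, hi, gran, sign)
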