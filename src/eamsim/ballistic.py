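"""Ballistic (noise-free within trial) accumulators: LBA and piecewise LBA.

The linear ballistic accumulator races two independent linear accumulators.
All randomness is between-trial: each accumulator starts at
k ~ Uniform[0, A] and climbs at a fixed rate d drawn from a normal
distribution (mean v_c for the accumulator matching the stimulus, v_e for
the mismatching one, common SD s) truncated to d > 0.  The first to reach
the threshold b wins; the response time is the winning crossing time
(b - k)/d plus the non-decision time t0.

The piecewise LBA models a mid-trial change in the stimulus evidence: until
decision time T* = swap_time + t_delay the race is a standard LBA; trials
still running at T* continue from their accrued evidence with post-change
drift rates.  By default the post-change drift keeps the trial's stage-1
drift *quantile* under the new means ("matched"), so a null change (same
means) leaves every trajectory untouched and the model reduces exactly to
the LBA; ``stage2_drift="independent"`` redraws stage-2 drifts afresh
instead (under which a null change still alters the RT tail, because
survival to T* selects slow stage-1 drifts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import truncnorm

from .trials import TrialSet

__all__ = ["LBAParams", "PLBAParams", "simulate_lba", "simulate_plba"]


@dataclass
class LBAParams:
    """Parameters of the two-alternative LBA.

    s defaults to 1 (the customary scaling constraint); s = 0 is allowed
    only as a degenerate point-mass drift for testing.  ``truncate_drift``
    selects between truncated-positive drifts (guaranteed termination, the
    default) and untruncated normal drifts, under which trials whose drifts
    are all non-positive never finish and are flagged non-terminated.
    """

    v_c: float
    v_e: float
    A: float
    b: float
    t0: float
    s: float = 1.0
    truncate_drift: bool = True

    def validate(self) -> None:
        if self.A < 0:
            raise ValueError(f"start-point range A must be >= 0; got {self.A}")
        if self.b < self.A:
            raise ValueError(f"threshold b ({self.b}) must be >= A ({self.A})")
        if self.s < 0:
            raise ValueError(f"drift SD s must be >= 0; got {self.s}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0; got {self.t0}")


@dataclass
class PLBAParams:
    """Piecewise LBA: stage-1 LBA plus post-change drifts and switch timing.

    ``swap_time`` is when the objective evidence changes and ``t_delay`` the
    lag before the new evidence takes effect; both are measured on the
    decision-time clock (t0 excluded).
    """

    stage1: LBAParams
    v2_c: float
    v2_e: float
    t_delay: float
    swap_time: float
    stage2_drift: str = "matched"

    def validate(self) -> None:
        self.stage1.validate()
        if self.t_delay < 0:
            raise ValueError(f"t_delay must be >= 0; got {self.t_delay}")
        if self.swap_time < 0:
            raise ValueError(f"swap_time must be >= 0; got {self.swap_time}")
        if self.stage2_drift not in ("matched", "independent"):
            raise ValueError(
                f"stage2_drift must be 'matched' or 'independent'; got {self.stage2_drift!r}"
            )


def _drifts_from_quantiles(
    u: np.ndarray, means: np.ndarray, s: float, truncate: bool
) -> np.ndarray:
    """Map uniform quantiles to drift rates via the (truncated) normal iCDF."""
    means = np.asarray(means, dtype=float)
    if s == 0.0:
        return np.broadcast_to(means, u.shape).copy()
    if truncate:
        a = (0.0 - means) / s
        return truncnorm.ppf(u, a, np.inf, loc=means, scale=s)
    return means + s * ndtri(u)


def _finish(times: np.ndarray, t0: float) -> TrialSet:
    tmin = times.min(axis=1)
    resp = np.argmin(times, axis=1) + 1
    nonterm = ~np.isfinite(tmin)
    resp[nonterm] = 0
    rt = t0 + tmin
    rt[nonterm] = np.nan
    return TrialSet(resp, rt)


def simulate_lba(n: int, params: LBAParams, rng: np.random.Generator) -> TrialSet:
    """Simulate ``n`` LBA trials.

    Draw order (fixed for reproducibility): start points for both
    accumulators, then drifts for accumulator 1, then accumulator 2.
    """
    params.validate()
    n = int(n)
    if n < 0:
        raise ValueError(f"trial count must be >= 0; got {n}")
    starts = rng.uniform(0.0, params.A, size=(n, 2)) if params.A > 0 else np.zeros((n, 2))
    u = rng.uniform(size=(n, 2))
    drifts = _drifts_from_quantiles(
        u, np.array([params.v_c, params.v_e]), params.s, params.truncate_drift
    )
    with np.errstate(divide="ignore"):
        times = np.where(drifts > 0, (params.b - starts) / drifts, np.inf)
    return _finish(times, params.t0)


def simulate_plba(n: int, params: PLBAParams, rng: np.random.Generator) -> TrialSet:
    """Simulate ``n`` piecewise-LBA trials.

    With the default ``stage2_drift="matched"`` the post-change drift
    reuses each trial's stage-1 quantile under the stage-2 means, so a
    null change reproduces the LBA exactly; ``"independent"`` draws fresh
    stage-2 quantiles.  The stage-1 random stream matches
    :func:`simulate_lba` under a shared seed in both modes.
    """
    params.validate()
    p1 = params.stage1
    n = int(n)
    if n < 0:
        raise ValueError(f"trial count must be >= 0; got {n}")
    starts = rng.uniform(0.0, p1.A, size=(n, 2)) if p1.A > 0 else np.zeros((n, 2))
    u1 = rng.uniform(size=(n, 2))
    d1 = _drifts_from_quantiles(u1, np.array([p1.v_c, p1.v_e]), p1.s, p1.truncate_drift)
    u2 = u1 if params.stage2_drift == "matched" else rng.uniform(size=(n, 2))
    d2 = _drifts_from_quantiles(
        u2, np.array([params.v2_c, params.v2_e]), p1.s, p1.truncate_drift
    )

    t_star = params.swap_time + params.t_delay
    with np.errstate(divide="ignore"):
        t1 = np.where(d1 > 0, (params.stage1.b - starts) / d1, np.inf)
    t1min = t1.min(axis=1)
    survives = ~(t1min <= t_star)

    times = t1.copy()
    if np.any(survives):
        x_star = starts[survives] + d1[survives] * t_star  # accrued evidence at T*
        with np.errstate(divide="ignore"):
            t_extra = np.where(d2[survives] > 0, (p1.b - x_star) / d2[survives], np.inf)
        times[survives] = t_star + t_extra
    return _finish(times, p1.t0)
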