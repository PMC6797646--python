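"""Euler–Maruyama simulators for stochastic evidence-accumulation models.

Three model families share one time-stepping core:

* **Diffusion** — a single relative-evidence process between two absorbing
  bounds: ``x <- x + v h + sigma sqrt(h) eps``, start z in (0, a), upper
  bound a (response 1), lower bound 0 (response 2), within-trial noise
  scale sigma fixed to 0.1 by convention.  The "full" model adds
  between-trial variability: drift ~ Normal(v, sv), start ~ U[z ± sz/2],
  non-decision time ~ U[ter ± ster/2].
* **LCA** — K racing accumulators with leakage lam, lateral inhibition
  beta and a reflecting floor at 0:
  ``x_i <- max(0, x_i + (v_i - lam x_i - beta sum_{j!=i} x_j) h
  + sigma sqrt(h) eps_i)``; the first accumulator to reach its threshold
  responds (ties go to the lowest index).
* **UGM** — momentary input low-pass filtered with time constant tau and
  multiplied by a linearly growing urgency signal:
  ``E <- E + (h/tau)(r - E)`` with ``r = v + sigma eps / sqrt(h)``, and
  decision variable ``y = E (u_intercept + u_slope * t_ms)`` compared
  against symmetric bounds ±a.

Each simulator takes an optional :class:`SchedulePack` carrying per-step
drift and/or threshold profiles (time-varying variants) or a piecewise
drift switch (drift changes to new values at decision time
swap_time + t_delay), and an optional :class:`~eamsim.lut.NormalLUT`: when
given, within-trial noise comes from the LUT-iCDF sampler, otherwise from
the exact normal generator.  Boundary checks are made after each update,
crossings are inclusive (>= / <=), and overshoot is not interpolated.
Trials still running after ``max_steps`` are returned with resp = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lut import NormalLUT, draw_standard_normal
from .trials import TrialSet

__all__ = [
    "DiffusionParams",
    "LCAParams",
    "UGMParams",
    "StepConfig",
    "PiecewiseSpec",
    "SchedulePack",
    "simulate_diffusion",
    "simulate_lca",
    "simulate_ugm",
    "wiener_absorption_prob",
    "linear_threshold_profile",
    "weibull_threshold_profile",
    "ugm_decision_variable",
]


@dataclass
class StepConfig:
    """Discretization: step ``h`` in seconds and the step budget."""

    h: float = 0.001
    max_steps: int = 5000

    def validate(self) -> None:
        if self.h <= 0:
            raise ValueError(f"time-step h must be > 0; got {self.h}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1; got {self.max_steps}")


@dataclass
class PiecewiseSpec:
    """Drift switch for piecewise variants.

    The new drifts ``v2`` (scalar, or one value per LCA accumulator) take
    effect at decision time ``swap_time + t_delay``.
    """

    swap_time: float
    t_delay: float
    v2: float | Sequence[float]

    def validate(self) -> None:
        if self.swap_time < 0 or self.t_delay < 0:
            raise ValueError("swap_time and t_delay must be >= 0")


@dataclass
class SchedulePack:
    """Optional per-step profiles for time-varying variants.

    ``drift_profile``: length-``max_steps`` vector (diffusion/UGM) or
    (max_steps, n_alt) matrix (LCA).  ``upper_profile``/``lower_profile``:
    per-step bounds for the diffusion; for the LCA the per-alternative
    threshold matrix is passed as ``upper_profile``.  ``piecewise`` is
    mutually exclusive with ``drift_profile``.
    """

    drift_profile: Optional[np.ndarray] = None
    upper_profile: Optional[np.ndarray] = None
    lower_profile: Optional[np.ndarray] = None
    piecewise: Optional[PiecewiseSpec] = None

    def __post_init__(self) -> None:
        for name in ("drift_profile", "upper_profile", "lower_profile"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.piecewise is not None and self.drift_profile is not None:
            raise ValueError("piecewise switch and drift_profile are mutually exclusive")


_EMPTY_SCHEDULE = SchedulePack()


@dataclass
class DiffusionParams:
    v: float
    a: float
    z: float
    ter: float
    sv: float = 0.0
    sz: float = 0.0
    ster: float = 0.0
    sigma: float = 0.1

    def validate(self) -> None:
        if not (0 < self.z < self.a):
            raise ValueError(f"need 0 < z < a; got z={self.z}, a={self.a}")
        if min(self.sv, self.sz, self.ster) < 0:
            raise ValueError("between-trial variabilities sv, sz, ster must be >= 0")
        if self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= self.a:
            raise ValueError("start-point range z ± sz/2 must stay inside (0, a)")
        if self.ter - self.ster / 2 < 0:
            raise ValueError("non-decision range ter ± ster/2 must stay >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class LCAParams:
    v: Sequence[float]
    b: float
    t0: float
    beta: float
    lam: float
    sigma: float = 0.1
    n_alt: int = field(default=0)  # 0 -> inferred from len(v)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.n_alt == 0:
            self.n_alt = int(self.v.shape[0])

    def validate(self) -> None:
        if self.v.shape[0] != self.n_alt:
            raise ValueError(f"len(v)={self.v.shape[0]} must equal n_alt={self.n_alt}")
        if self.n_alt < 2:
            raise ValueError("LCA needs at least 2 response alternatives")
        if self.b <= 0:
            raise ValueError("threshold b must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")


@dataclass
class UGMParams:
    v: float
    a: float
    ter: float
    tau: float = 0.1
    u_slope: float = 1.0  # urgency gain per millisecond
    u_intercept: float = 0.0
    sigma: float = 0.1

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("filter time constant tau must be > 0")
        if self.a <= 0:
            raise ValueError("threshold a must be > 0")
        if self.u_slope < 0:
            raise ValueError("urgency slope must be >= 0")
        if self.sigma < 0 or self.ter < 0:
            raise ValueError("sigma and ter must be >= 0")


def _noise_fn(lut: Optional[NormalLUT]):
    if lut is None:
        return lambda rng, size: rng.standard_normal(size)
    return lambda rng, size: draw_standard_normal(lut, size, rng)


def _profile(profile: Optional[np.ndarray], max_steps: int, name: str, ncol: int = 0):
    """Validate a schedule profile against the step budget; None passes through."""
    if profile is None:
        return None
    profile = np.asarray(profile, dtype=float)
    if profile.shape[0] != max_steps:
        raise ValueError(
            f"{name} has {profile.shape[0]} rows but max_steps={max_steps}"
        )
    if ncol and (profile.ndim != 2 or profile.shape[1] != ncol):
        raise ValueError(f"{name} must have {ncol} columns, one per alternative")
    return profile


def _swap_step(piecewise: Optional[PiecewiseSpec], h: float, max_steps: int) -> int:
    if piecewise is None:
        return max_steps + 1
    piecewise.validate()
    t_star = piecewise.swap_time + piecewise.t_delay
    return int(math.ceil(t_star / h))


def simulate_diffusion(
    n: int,
    params: DiffusionParams,
    step: Optional[StepConfig] = None,
    schedule: Optional[SchedulePack] = None,
    lut: Optional[NormalLUT] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialSet:
    """Simulate first passages of the (full) diffusion model.

    Response 1 = upper bound, 2 = lower bound.  Schedules: per-step drift
    vector, per-step upper/lower bound vectors, or a piecewise drift
    switch.  With ``lut`` given, the within-trial increments use LUT-iCDF
    noise.
    """
    params.validate()
    step = step or StepConfig()
    step.validate()
    schedule = schedule or _EMPTY_SCHEDULE
    rng = rng if rng is not None else np.random.default_rng()
    n = int(n)
    if n < 0:
        raise ValueError(f"trial count must be >= 0; got {n}")

    h, m = step.h, step.max_steps
    drift_prof = _profile(schedule.drift_profile, m, "drift_profile")
    upper = _profile(schedule.upper_profile, m, "upper_profile")
    lower = _profile(schedule.lower_profile, m, "lower_profile")
    if upper is not None and lower is not None and np.any(upper <= lower):
        raise ValueError("upper_profile must exceed lower_profile at every step")
    swap_at = _swap_step(schedule.piecewise, h, m)
    noise = _noise_fn(lut)
    sqh = math.sqrt(h)

    # between-trial parameter draws (fixed order)
    dev1 = rng.normal(0.0, params.sv, size=n) if params.sv > 0 else np.zeros(n)
    z_tr = params.z + (rng.uniform(-0.5, 0.5, size=n) * params.sz if params.sz > 0 else 0.0)
    ter_tr = params.ter + (
        rng.uniform(-0.5, 0.5, size=n) * params.ster if params.ster > 0 else 0.0
    )
    if schedule.piecewise is not None:
        v2 = float(np.asarray(schedule.piecewise.v2).reshape(()))
        dev2 = rng.normal(0.0, params.sv, size=n) if params.sv > 0 else np.zeros(n)
    x = np.asarray(z_tr, dtype=float).copy() if np.ndim(z_tr) else np.full(n, z_tr, dtype=float)

    resp = np.zeros(n, dtype=np.int64)
    steps_taken = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    for k in range(m):
        if k < swap_at:
            mu = drift_prof[k] if drift_prof is not None else params.v
            drift = mu + dev1[active]
        else:
            drift = v2 + dev2[active]
        eps = noise(rng, active.size)
        xa = x[active] + drift * h + params.sigma * sqh * eps
        up = upper[k] if upper is not None else params.a
        lo = lower[k] if lower is not None else 0.0
        hit_up = xa >= up
        hit_lo = (xa <= lo) & ~hit_up
        done = hit_up | hit_lo
        if np.any(done):
            resp[active[hit_up]] = 1
            resp[active[hit_lo]] = 2
            steps_taken[active[done]] = k + 1
        x[active] = xa
        active = active[~done]
        if active.size == 0:
            break

    rt = np.where(resp > 0, ter_tr + steps_taken * h, np.nan)
    return TrialSet(resp, rt)


def simulate_lca(
    n: int,
    params: LCAParams,
    step: Optional[StepConfig] = None,
    schedule: Optional[SchedulePack] = None,
    lut: Optional[NormalLUT] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialSet:
    """Simulate the leaky competing accumulator.

    All accumulators start at 0; the reflecting floor is applied after the
    full update including noise.  Time-varying thresholds are accepted as a
    per-alternative matrix in ``schedule.upper_profile``.
    """
    params.validate()
    step = step or StepConfig()
    step.validate()
    schedule = schedule or _EMPTY_SCHEDULE
    rng = rng if rng is not None else np.random.default_rng()
    n = int(n)
    if n < 0:
        raise ValueError(f"trial count must be >= 0; got {n}")
    if schedule.lower_profile is not None:
        raise ValueError("LCA has no lower bound; lower_profile is not accepted")

    h, m, ka = step.h, step.max_steps, params.n_alt
    drift_prof = _profile(schedule.drift_profile, m, "drift_profile", ncol=ka)
    thresh = _profile(schedule.upper_profile, m, "threshold matrix", ncol=ka)
    swap_at = _swap_step(schedule.piecewise, h, m)
    if schedule.piecewise is not None:
        v2 = np.broadcast_to(np.asarray(schedule.piecewise.v2, dtype=float), (ka,))
    noise = _noise_fn(lut)
    sqh = math.sqrt(h)

    x = np.zeros((n, ka))
    resp = np.zeros(n, dtype=np.int64)
    steps_taken = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    for k in range(m):
        if k < swap_at:
            mu = drift_prof[k] if drift_prof is not None else params.v
        else:
            mu = v2
        eps = noise(rng, (active.size, ka))
        xa = x[active]
        total = xa.sum(axis=1, keepdims=True)
        xa = xa + (mu - params.lam * xa - params.beta * (total - xa)) * h
        xa += params.sigma * sqh * eps
        np.maximum(xa, 0.0, out=xa)
        bk = thresh[k] if thresh is not None else params.b
        crossed = xa >= bk
        done = crossed.any(axis=1)
        if np.any(done):
            winner = np.argmax(crossed[done], axis=1)  # lowest index wins ties
            resp[active[done]] = winner + 1
            steps_taken[active[done]] = k + 1
        x[active] = xa
        active = active[~done]
        if active.size == 0:
            break

    rt = np.where(resp > 0, params.t0 + steps_taken * h, np.nan)
    return TrialSet(resp, rt)


def simulate_ugm(
    n: int,
    params: UGMParams,
    step: Optional[StepConfig] = None,
    schedule: Optional[SchedulePack] = None,
    lut: Optional[NormalLUT] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialSet:
    """Simulate the urgency-gating model (time-varying drift supported)."""
    params.validate()
    step = step or StepConfig()
    step.validate()
    schedule = schedule or _EMPTY_SCHEDULE
    rng = rng if rng is not None else np.random.default_rng()
    n = int(n)
    if n < 0:
        raise ValueError(f"trial count must be >= 0; got {n}")
    if schedule.piecewise is not None or schedule.upper_profile is not None or (
        schedule.lower_profile is not None
    ):
        raise ValueError("UGM accepts a drift profile only (no piecewise/threshold schedules)")

    h, m = step.h, step.max_steps
    drift_prof = _profile(schedule.drift_profile, m, "drift_profile")
    noise = _noise_fn(lut)
    sqh = math.sqrt(h)
    alpha = h / params.tau

    e = np.zeros(n)
    resp = np.zeros(n, dtype=np.int64)
    steps_taken = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    for k in range(m):
        mu = drift_prof[k] if drift_prof is not None else params.v
        eps = noise(rng, active.size)
        r = mu + params.sigma * eps / sqh
        ea = e[active] + alpha * (r - e[active])
        t_ms = (k + 1) * h * 1000.0
        y = ea * (params.u_intercept + params.u_slope * t_ms)
        hit_up = y >= params.a
        hit_lo = (y <= -params.a) & ~hit_up
        done = hit_up | hit_lo
        if np.any(done):
            resp[active[hit_up]] = 1
            resp[active[hit_lo]] = 2
            steps_taken[active[done]] = k + 1
        e[active] = ea
        active = active[~done]
        if active.size == 0:
            break

    rt = np.where(resp > 0, params.ter + steps_taken * h, np.nan)
    return TrialSet(resp, rt)


def ugm_decision_variable(
    params: UGMParams, step: StepConfig, drift_profile: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free UGM trajectories (filtered evidence E_k and y_k), k = 1..max_steps.

    Useful for inspecting the filter/urgency interplay and as a
    deterministic reference for the sigma = 0 limit of the simulator.
    """
    params.validate()
    step.validate()
    m = step.max_steps
    mu = np.full(m, params.v) if drift_profile is None else np.asarray(drift_profile, float)
    alpha = step.h / params.tau
    e = np.empty(m)
    acc = 0.0
    for k in range(m):
        acc = acc + alpha * (mu[k] - acc)
        e[k] = acc
    t_ms = np.arange(1, m + 1) * step.h * 1000.0
    return e, e * (params.u_intercept + params.u_slope * t_ms)


def wiener_absorption_prob(v: float, a: float, z: float, sigma: float = 0.1) -> float:
    """Closed-form upper-bound absorption probability of a Wiener process.

    P(hit a before 0 | start z) = (1 - exp(-2 v z / sigma^2))
    / (1 - exp(-2 v a / sigma^2)), with the drift-free limit z / a.
    """
    if not (0 < z < a):
        raise ValueError(f"need 0 < z < a; got z={z}, a={a}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    c = 2.0 * v / sigma**2
    if abs(c) * a < 1e-12:
        return z / a
    return float(np.expm1(-c * z) / np.expm1(-c * a))


def linear_threshold_profile(
    max_steps: int, h: float, a0: float, rate: float, floor: float = 0.0
) -> np.ndarray:
    """Linearly collapsing bound: a(t) = max(a0 - rate * t, floor)."""
    t = np.arange(1, max_steps + 1) * h
    return np.maximum(a0 - rate * t, floor)


def weibull_threshold_profile(
    max_steps: int, h: float, a0: float, a_inf: float, scale: float, shape: float
) -> np.ndarray:
    """Weibull-type collapse from a0 toward a_inf with time scale/shape.

    a(t) = a_inf + (a0 - a_inf) * exp(-(t/scale)^shape) — the three free
    quantities (asymptote, scale, shape) give the customary flexible
    collapsing-bound family.
    """
    if scale <= 0 or shape <= 0:
        raise ValueError("scale and shape must be > 0")
    t = np.arange(1, max_steps + 1) * h
    return a_inf + (a0 - a_inf) * np.exp(-((t / scale) ** shape))
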