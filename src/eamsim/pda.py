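"""Probability density approximation (PDA) pseudo-likelihood.

Models without a tractable first-passage density can still be fit by
likelihood methods: simulate a large number of trials at the candidate
parameters, kernel-smooth the simulated RTs of each response alternative
into a *defective* density (scaled by that alternative's response
proportion, so the densities jointly integrate to the terminated fraction),
and read off the density at each observed (response, RT) pair by linear
interpolation on a fixed grid.  Summing log densities over trials and
conditions yields the pseudo-log-likelihood.

Smoothing follows the classic binned-convolution KDE: simulated RTs are
linearly binned onto a 512-point grid spanning [min - 3 bw, max + 3 bw] and
convolved with a Gaussian kernel of bandwidth ``bw`` (Silverman's rule of
thumb on the simulated sample by default).  Densities are floored at a
small positive constant so the log-likelihood is always finite.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .trials import TrialSet

__all__ = [
    "Dataset",
    "PDAResult",
    "DegenerateSampleError",
    "silverman_bandwidth",
    "defective_kde",
    "log_dens_like",
    "DENSITY_FLOOR",
    "GRID_SIZE",
]

DENSITY_FLOOR = 1e-10
GRID_SIZE = 512


class DegenerateSampleError(ValueError):
    """Raised when a bandwidth cannot be computed (n < 2 or zero spread)."""


@dataclass
class Dataset:
    """Observed trials: condition label, chosen alternative (>=1), RT in seconds."""

    cond: np.ndarray
    resp: np.ndarray
    time: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond)
        self.resp = np.asarray(self.resp, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if not (len(self.cond) == len(self.resp) == len(self.time)):
            raise ValueError("cond, resp and time must have equal length")
        if len(self.resp) and (self.resp.min() < 1 or self.time.min() <= 0):
            raise ValueError("observed trials require resp >= 1 and time > 0")

    def __len__(self) -> int:
        return len(self.resp)

    def conditions(self) -> list:
        return sorted(np.unique(self.cond).tolist())


@dataclass
class PDAResult:
    """Approximated densities per response alternative + non-termination count."""

    densities_by_resp: dict
    n_nonterminated: int


def silverman_bandwidth(rts: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(SD, IQR/1.34) n^(-1/5)."""
    rts = np.asarray(rts, dtype=float)
    n = rts.size
    if n < 2:
        raise DegenerateSampleError(f"bandwidth needs >= 2 points; got {n}")
    sd = float(np.std(rts, ddof=1))
    q75, q25 = np.percentile(rts, [75.0, 25.0])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        raise DegenerateSampleError("sample has zero spread; bandwidth undefined")
    return 0.9 * spread * n ** (-0.2)


def _kde_grid(samples: np.ndarray, bw: float):
    """Gaussian KDE by linear binning + discrete Gaussian convolution."""
    lo = samples.min() - 3.0 * bw
    hi = samples.max() + 3.0 * bw
    grid = np.linspace(lo, hi, GRID_SIZE)
    dx = grid[1] - grid[0]
    # linear binning preserves first moments within each cell
    pos = (samples - lo) / dx
    left = np.floor(pos).astype(np.int64)
    frac = pos - left
    counts = np.zeros(GRID_SIZE)
    np.add.at(counts, np.clip(left, 0, GRID_SIZE - 1), 1.0 - frac)
    np.add.at(counts, np.clip(left + 1, 0, GRID_SIZE - 1), frac)
    smooth = gaussian_filter1d(counts, sigma=bw / dx, mode="constant", truncate=6.0)
    return grid, smooth / (samples.size * dx)


def defective_kde(
    sim: TrialSet,
    query_rts_by_resp: Mapping[int, np.ndarray],
    bandwidth: Optional[float] = None,
    defective: bool = True,
    floor: float = DENSITY_FLOOR,
) -> PDAResult:
    """Defective kernel densities of simulated RTs at the observed RTs.

    Per alternative ``r`` the Gaussian KDE of the simulated RTs with
    ``resp == r`` is evaluated by linear interpolation and scaled by
    ``count(resp == r) / len(sim)`` (total *includes* non-terminated
    trials), so choice probabilities enter the likelihood; pass
    ``defective=False`` for plain conditional densities.  ``bandwidth``
    ``None`` applies Silverman's rule per alternative.  Query points
    outside the grid, and alternatives with a degenerate simulated sample,
    get the floor.
    """
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError(f"bandwidth must be > 0; got {bandwidth}")
    total = len(sim)
    out: dict = {}
    for r, queries in query_rts_by_resp.items():
        queries = np.asarray(queries, dtype=float)
        sim_rts = sim.rt[sim.resp == r]
        try:
            bw = bandwidth if bandwidth is not None else silverman_bandwidth(sim_rts)
        except DegenerateSampleError:
            out[r] = np.full(queries.shape, floor)
            continue
        grid, dens = _kde_grid(sim_rts, bw)
        if defective and total > 0:
            dens = dens * (sim_rts.size / total)
        vals = np.interp(queries, grid, dens, left=0.0, right=0.0)
        out[r] = np.maximum(vals, floor)
    return PDAResult(densities_by_resp=out, n_nonterminated=sim.n_nonterminated)


def _call_simulator(model: Callable, n: int, params, rng, step, schedule, lut) -> TrialSet:
    """Forward step/schedule/lut only if the simulator accepts them (LBA does not)."""
    sig = inspect.signature(model)
    kwargs = {}
    for name, val in (("step", step), ("schedule", schedule), ("lut", lut)):
        if name in sig.parameters:
            kwargs[name] = val
    if "rng" in sig.parameters:
        kwargs["rng"] = rng
        return model(n, params, **kwargs)
    return model(n, params, rng, **kwargs)


def log_dens_like(
    params_by_cond: Mapping,
    data: Dataset,
    model: Callable[..., TrialSet],
    conds: Optional[Sequence] = None,
    bandwidth: float | str = "silverman",
    n_sim: int = 10_000,
    step=None,
    schedule=None,
    lut=None,
    rng: Optional[np.random.Generator] = None,
    defective: bool = True,
    floor: float = DENSITY_FLOOR,
    return_details: bool = False,
):
    """PDA pseudo-log-likelihood of ``data`` under ``model``.

    For each condition, ``n_sim`` trials are simulated at that condition's
    parameters, smoothed into defective densities, and the log densities of
    the condition's observed (resp, rt) pairs are summed; the grand total
    over conditions is returned.  With ``return_details=True`` also returns
    a dict with per-condition non-termination counts (available for an
    additive penalty; none is applied by default).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if conds is None:
        conds = data.conditions()
    data_conds = set(np.unique(data.cond).tolist())
    missing = data_conds - set(conds)
    if missing:
        raise ValueError(f"data contains conditions not listed in conds: {sorted(missing)}")
    missing_params = data_conds - set(params_by_cond)
    if missing_params:
        raise ValueError(f"no parameters supplied for conditions: {sorted(missing_params)}")
    bw = None if bandwidth == "silverman" else float(bandwidth)

    total_ll = 0.0
    nonterm: dict = {}
    for cond in conds:
        mask = data.cond == cond
        if not np.any(mask):
            continue
        sim = _call_simulator(model, n_sim, params_by_cond[cond], rng, step, schedule, lut)
        queries = {
            int(r): data.time[mask & (data.resp == r)]
            for r in np.unique(data.resp[mask])
        }
        res = defective_kde(sim, queries, bandwidth=bw, defective=defective, floor=floor)
        nonterm[cond] = res.n_nonterminated
        total_ll += float(sum(np.log(d).sum() for d in res.densities_by_resp.values()))
    if return_details:
        return total_ll, {"n_nonterminated": nonterm}
    return total_ll
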