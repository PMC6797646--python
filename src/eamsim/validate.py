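"""KS-based accuracy harness for the LUT-iCDF approximation.

Compares LUT-iCDF draws against an exact normal generator — either on the
raw samples ("normal" context) or through a model simulation, pooling
signed RTs (alternative-2 RTs negated) so one two-sample KS statistic
summarizes choice proportions and RT distributions jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import ks_2samp

from . import sde
from .lut import NormalLUT, build_lut, draw_standard_normal

__all__ = ["KSReport", "ks_two_sample", "validate_granularity", "MODEL_CONTEXTS"]


@dataclass
class KSReport:
    granularity: float
    n: int
    ks_stat: float
    p_value: float
    context: str
    per_resp: dict = field(default_factory=dict)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS statistic (sup ECDF distance) and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison requires two non-empty samples")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# Reference parameterizations for the model contexts (the within-trial-noise
# models, where LUT noise enters the dynamics).  Values give mid-range
# accuracy/RT behaviour with most mass terminating well inside the budget.
MODEL_CONTEXTS = {
    "diffusion": lambda: (
        sde.simulate_diffusion,
        sde.DiffusionParams(v=0.15, a=0.1, z=0.05, ter=0.3),
    ),
    "lca": lambda: (
        sde.simulate_lca,
        sde.LCAParams(v=[0.4, 0.3], b=0.12, t0=0.3, beta=1.0, lam=1.0),
    ),
    "ugm": lambda: (
        sde.simulate_ugm,
        sde.UGMParams(v=0.15, a=40.0, ter=0.3, tau=0.1),
    ),
}


def validate_granularity(
    granularity: float,
    n: int,
    model_or_normal: str = "normal",
    seed: Optional[int] = None,
    step: Optional[sde.StepConfig] = None,
) -> KSReport:
    """KS comparison of LUT-iCDF vs exact-normal sampling at one granularity.

    ``model_or_normal``: "normal" compares raw draws; a model name
    ("diffusion", "lca", "ugm") simulates ``n`` trials under each noise
    source and compares pooled signed RTs (per-alternative KS statistics
    are reported alongside).
    """
    lut = build_lut(granularity)
    rng = np.random.default_rng(seed)
    if model_or_normal == "normal":
        a = draw_standard_normal(lut, n, rng)
        b = rng.standard_normal(n)
        stat, p = ks_two_sample(a, b)
        return KSReport(granularity, n, stat, p, "normal")
    if model_or_normal not in MODEL_CONTEXTS:
        raise ValueError(
            f"unknown context {model_or_normal!r}; choose 'normal' or one of "
            f"{sorted(MODEL_CONTEXTS)}"
        )
    simulate, params = MODEL_CONTEXTS[model_or_normal]()
    sim_lut = simulate(n, params, step=step, lut=lut, rng=rng)
    sim_exact = simulate(n, params, step=step, lut=None, rng=rng)
    stat, p = ks_two_sample(sim_lut.signed_rt(), sim_exact.signed_rt())
    per_resp = {}
    for r in (1, 2):
        x = sim_lut.rt[sim_lut.resp == r]
        y = sim_exact.rt[sim_exact.resp == r]
        if x.size and y.size:
            per_resp[r] = ks_two_sample(x, y)
    return KSReport(granularity, n, stat, p, model_or_normal, per_resp)
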