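"""CSV / config I/O: observed datasets, simulated trials, parameter configs,
and per-step schedule profiles.

Dataset CSV contract: header ``Cond,Resp,Time`` (Time in seconds).
Simulated trials are written in the same layout, with non-terminated trials
carrying ``Resp=0`` and an empty Time field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ballistic, sde
from .pda import Dataset
from .trials import TrialSet

__all__ = [
    "DatasetFormatError",
    "read_dataset",
    "read_trials",
    "write_trials",
    "load_config",
    "params_from_config",
    "step_from_config",
    "read_profiles",
]

REQUIRED_COLUMNS = ["Cond", "Resp", "Time"]


class DatasetFormatError(ValueError):
    """Malformed dataset CSV (missing columns, non-numeric fields, ...)."""


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype={"Cond": str})
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path}: file is empty (expected header Cond,Resp,Time)")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required column(s) {missing}")
    for col in ("Resp", "Time"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col == "Time":
            bad &= ~(df[col].astype(str).str.strip() == "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetFormatError(
                f"{path}: non-numeric {col} value {df[col].iloc[row]!r} at data row {row + 1}"
            )
        df[col] = coerced
    return df


def read_dataset(path) -> Dataset:
    """Read observed trials (all terminated: Resp >= 1, Time > 0)."""
    df = _read_table(path)
    if df["Resp"].isna().any() or df["Time"].isna().any():
        row = int(df.index[df["Resp"].isna() | df["Time"].isna()][0])
        raise DatasetFormatError(f"{path}: missing Resp/Time at data row {row + 1}")
    return Dataset(
        cond=df["Cond"].to_numpy(),
        resp=df["Resp"].to_numpy(dtype=np.int64),
        time=df["Time"].to_numpy(dtype=float),
    )


def read_trials(path) -> TrialSet:
    """Read simulated trials; Resp=0 rows (empty Time) become non-terminated."""
    df = _read_table(path)
    resp = df["Resp"].fillna(0).to_numpy(dtype=np.int64)
    rt = df["Time"].to_numpy(dtype=float)
    return TrialSet(resp, np.where(resp > 0, rt, np.nan))


def write_trials(trials: TrialSet, path, cond="1") -> None:
    """Write a TrialSet as Cond,Resp,Time CSV (full float precision)."""
    with open(path, "w") as fh:
        fh.write("Cond,Resp,Time\n")
        for r, t in zip(trials.resp, trials.rt):
            time_field = "" if r == 0 else repr(float(t))
            fh.write(f"{cond},{int(r)},{time_field}\n")


def load_config(path) -> dict:
    """Load a JSON or YAML parameter config."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


# Named-parameter config keys per model (conventional short names).
def params_from_config(model: str, cfg: dict):
    """Build a params object for ``model`` from named config keys.

    Keys: lba ``vc, ve, A, b, t0[, s]``; plba additionally
    ``v2c, v2e, tdelay, swaptime``; diffusion
    ``v, a, z, ter[, sv, sz, ster, sigma]``; lca
    ``v (list), b, t0, beta, lam[, sigma, nRespAlt]``; ugm
    ``v, a, ter[, tau, uslope, uintercept, sigma]``.
    """
    model = model.lower()
    try:
        if model == "lba":
            return ballistic.LBAParams(
                v_c=cfg["vc"], v_e=cfg["ve"], A=cfg["A"], b=cfg["b"],
                t0=cfg["t0"], s=cfg.get("s", 1.0),
            )
        if model == "plba":
            return ballistic.PLBAParams(
                stage1=ballistic.LBAParams(
                    v_c=cfg["vc"], v_e=cfg["ve"], A=cfg["A"], b=cfg["b"],
                    t0=cfg["t0"], s=cfg.get("s", 1.0),
                ),
                v2_c=cfg["v2c"], v2_e=cfg["v2e"],
                t_delay=cfg["tdelay"], swap_time=cfg["swaptime"],
                stage2_drift=cfg.get("stage2drift", "matched"),
            )
        if model == "diffusion":
            return sde.DiffusionParams(
                v=cfg["v"], a=cfg["a"], z=cfg["z"], ter=cfg["ter"],
                sv=cfg.get("sv", 0.0), sz=cfg.get("sz", 0.0),
                ster=cfg.get("ster", 0.0), sigma=cfg.get("sigma", 0.1),
            )
        if model == "lca":
            return sde.LCAParams(
                v=cfg["v"], b=cfg["b"], t0=cfg["t0"], beta=cfg["beta"],
                lam=cfg["lam"], sigma=cfg.get("sigma", 0.1),
                n_alt=cfg.get("nRespAlt", 0),
            )
        if model == "ugm":
            return sde.UGMParams(
                v=cfg["v"], a=cfg["a"], ter=cfg["ter"], tau=cfg.get("tau", 0.1),
                u_slope=cfg.get("uslope", 1.0),
                u_intercept=cfg.get("uintercept", 0.0),
                sigma=cfg.get("sigma", 0.1),
            )
    except KeyError as exc:
        raise ValueError(f"config for model {model!r} is missing key {exc}") from None
    raise ValueError(f"unknown model {model!r}")


def step_from_config(cfg: dict) -> sde.StepConfig:
    return sde.StepConfig(h=cfg.get("h", 0.001), max_steps=cfg.get("maxiter", 5000))


def read_profiles(path, max_steps: int, n_alt: int = 0) -> sde.SchedulePack:
    """Read per-step schedule profiles from CSV.

    Columns: ``v`` (or ``v1..vK`` for the LCA), ``aU``, ``aL`` (or
    ``a1..aK`` for per-alternative LCA thresholds); row count must equal
    ``max_steps``.
    """
    df = pd.read_csv(path)
    if len(df) != max_steps:
        raise ValueError(f"{path}: profile has {len(df)} rows; expected max_steps={max_steps}")
    drift = upper = lower = None
    if "v" in df.columns:
        drift = df["v"].to_numpy(dtype=float)
    else:
        vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        if vcols:
            vcols.sort(key=lambda c: int(c[1:]))
            drift = df[vcols].to_numpy(dtype=float)
    acols = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
    if acols:
        acols.sort(key=lambda c: int(c[1:]))
        upper = df[acols].to_numpy(dtype=float)
    if "aU" in df.columns:
        upper = df["aU"].to_numpy(dtype=float)
    if "aL" in df.columns:
        lower = df["aL"].to_numpy(dtype=float)
    return sde.SchedulePack(drift_profile=drift, upper_profile=upper, lower_profile=lower)
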