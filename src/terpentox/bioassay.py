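"""Bioluminescence-inhibition assay processing.

Raw luminometer kinetics (RLU per condition/replicate/time) become the
percent-inhibition endpoint used as the QSAR activity, and serial-dilution
(CFU, RLU) pairs calibrate the luminescent signal against viable counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "CONTROL"
TIME_GRID = (0, 20, 40, 60, 80, 100)  # minutes

RLU_COLUMNS = ["condition", "concentration_uM", "replicate", "time_min", "rlu"]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of log10 RLU against log10 CFU/mL."""

    slope: float
    intercept: float
    r2: float


def percent_inhibition(gc: float | np.ndarray, gs: float | np.ndarray) -> float | np.ndarray:
    """Bioluminescence inhibition ((Gc - Gs)/Gc) * 100, in percent.

    Gc is the mean control signal, Gs the sample signal. Negative values
    (stimulation above the control) are preserved.
    """
    gc_arr = np.asarray(gc, dtype=float)
    if np.any(gc_arr <= 0):
        raise ValueError("control signal Gc must be > 0")
    if np.any(np.asarray(gs, dtype=float) < 0):
        raise ValueError("sample signal Gs must be >= 0")
    out = (gc_arr - np.asarray(gs, dtype=float)) / gc_arr * 100.0
    return float(out) if out.ndim == 0 else out


def read_luminescence(path: str | Path) -> pd.DataFrame:
    """Read a tidy RLU kinetics CSV (condition, concentration_uM, replicate,
    time_min, rlu), validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in RLU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["rlu"] < 0).any():
        raise ValueError(f"{path}: negative RLU values")
    return df


def inhibition_table(
    series: pd.DataFrame,
    control_label: str = CONTROL,
    time_matched_control: bool = True,
) -> pd.DataFrame:
    """Per (compound, concentration, time) mean percent inhibition.

    Each replicate's inhibition is computed against the replicate-averaged
    control at the same time point (or, with ``time_matched_control=False``,
    against the t=0 control mean); replicates are then averaged with an
    n-1 standard deviation.
    """
    df = series.copy()
    missing = [c for c in RLU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input is missing columns {missing}")
    ctrl = df[df["condition"] == control_label]
    if ctrl.empty:
        raise ValueError(f"no control rows (condition == {control_label!r})")
    samples = df[df["condition"] != control_label]
    ctrl_mean = ctrl.groupby("time_min")["rlu"].mean()

    needed = sorted(samples["time_min"].unique())
    gaps = [t.item() if hasattr(t, "item") else t for t in needed if t not in ctrl_mean.index]
    if gaps:
        raise ValueError(f"control missing at time point(s): {gaps}")

    if time_matched_control:
        gc_of = lambda t: float(ctrl_mean.loc[t])  # noqa: E731
    else:
        if 0 not in ctrl_mean.index:
            raise ValueError("control missing at time point(s): [0]")
        gc0 = float(ctrl_mean.loc[0])
        gc_of = lambda t: gc0  # noqa: E731

    rows = []
    for (comp, conc, t), grp in samples.groupby(
        ["condition", "concentration_uM", "time_min"], sort=True
    ):
        inh = percent_inhibition(gc_of(t), grp["rlu"].to_numpy())
        inh = np.atleast_1d(inh)
        rows.append(
            {
                "compound": comp,
                "concentration_uM": conc,
                "time_min": t,
                "mean_inhibition": float(np.mean(inh)),
                "sd": float(np.std(inh, ddof=1)) if len(inh) > 1 else 0.0,
                "n": int(len(inh)),
            }
        )
    return pd.DataFrame(rows)


def select_endpoint(
    table: pd.DataFrame,
    time: float = 20,
    concentration: float | None = None,
) -> pd.Series:
    """Activity vector for the QSAR: mean percent inhibition at the chosen
    incubation time, one value per compound at a fixed concentration."""
    if time not in set(table["time_min"]):
        raise ValueError(f"time {time} min not present in the table")
    sub = table[table["time_min"] == time]
    if concentration is not None:
        sub = sub[sub["concentration_uM"] == concentration]
        if sub.empty:
            raise ValueError(f"no rows at concentration {concentration} uM")
    elif sub["concentration_uM"].nunique() > 1:
        raise ValueError(
            "multiple concentrations present; pass `concentration` to select one"
        )
    y = sub.set_index("compound")["mean_inhibition"].sort_index()
    y.name = f"inhibition_pct_t{int(time)}"
    return y


def calibration_fit(
    cfu: Sequence[float] | np.ndarray, rlu: Sequence[float] | np.ndarray
) -> CalibrationFit:
    """OLS of log10 RLU on log10 CFU/mL over serial-dilution pairs."""
    cfu = np.asarray(cfu, dtype=float)
    rlu = np.asarray(rlu, dtype=float)
    if cfu.shape != rlu.shape:
        raise ValueError("cfu and rlu must have the same length")
    if len(cfu) < 3:
        raise ValueError("insufficient points: need >= 3 (CFU, RLU) pairs")
    if np.any(cfu <= 0) or np.any(rlu <= 0):
        raise ValueError("CFU and RLU values must be > 0 for the log-log fit")
    res = stats.linregress(np.log10(cfu), np.log10(rlu))
    return CalibrationFit(
        slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2)
    )
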