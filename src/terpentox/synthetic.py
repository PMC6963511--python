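"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators: a correlated Gaussian descriptor matrix with planted
pathological columns and a sparse linear activity signal (exercising the
pre-screen and the subset search with a known answer), and bioluminescence
decay kinetics with a concentration-dependent inhibition plateau whose onset
saturates within the first sampling interval (exercising the assay
pipeline). A packaged scenario table carries per-compound plateau levels at
the four assay concentrations so the kinetics generator can imitate the
study's qualitative inhibition pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioassay import CONTROL, TIME_GRID
from .descriptors import DescriptorMatrix, DescriptorMeta

_SYNTH_CATEGORY = "topological"  # nominal category tag for generated columns


@dataclass(frozen=True)
class SynthConfig:
    """Descriptor-matrix generator settings.

    Defaults mirror the study geometry: 27 compounds, a screened pool of 60
    informative-scale descriptors in correlated blocks, 4 active descriptors
    carrying the linear signal.
    """

    n_compounds: int = 27
    p_descriptors: int = 60
    n_active: int = 4
    # intercept first; equal-magnitude alternating signs keep every active
    # descriptor equally identifiable at a given population R²
    beta: tuple[float, ...] = (5.0, 2.0, -2.0, 2.0, -2.0)
    noise_sd: float = 4.0 / 3.0  # population R² = 0.9 for the default beta
    block_size: int = 5
    rho: float = 0.3
    n_constant: int = 1
    n_missing: int = 1
    n_duplicate: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active > self.p_descriptors:
            raise ValueError("n_active must not exceed p_descriptors")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.beta) != self.n_active + 1:
            raise ValueError("beta must hold the intercept plus one coefficient per active column")


@dataclass(frozen=True)
class LumSimConfig:
    """Luminescence kinetics generator settings.

    ``gc0`` is the control signal at t=0 (RLU), ``k_c`` its slow exponential
    decay (1/min), ``tau`` the inhibition onset time constant (min; small
    against the 20-min sampling step so the plateau is reached by the first
    sampled time), ``cv`` the multiplicative lognormal replicate noise.
    """

    gc0: float = 2.0e5
    k_c: float = 0.002
    tau: float = 6.0
    cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.gc0 <= 0 or self.tau <= 0:
            raise ValueError("gc0 and tau must be > 0")


@dataclass
class MatrixTruth:
    """Ground truth recorded alongside a generated descriptor matrix."""

    active: list[str]
    beta: dict[str, float]
    intercept: float
    pathological: dict[str, str]  # column -> expected prescreen rule
    duplicate_sources: dict[str, str] = field(default_factory=dict)


def gen_descriptor_matrix(cfg: SynthConfig) -> tuple[DescriptorMatrix, MatrixTruth]:
    """Correlated Gaussian descriptor blocks plus planted pathological columns.

    Informative columns come in equicorrelated blocks (within-block
    correlation ``rho``); the first column of each of the first ``n_active``
    blocks is active, so active descriptors are mutually near-orthogonal.
    Pathological columns (constant, missing-value, duplicate-collinear) are
    appended with their expected prescreen elimination tags recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_compounds, cfg.p_descriptors
    n_blocks = int(np.ceil(p / cfg.block_size))
    cols = []
    for b in range(n_blocks):
        width = min(cfg.block_size, p - b * cfg.block_size)
        common = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        block = np.sqrt(cfg.rho) * common + np.sqrt(1 - cfg.rho) * own
        cols.append(block)
    X = np.hstack(cols)[:, :p]
    names = [f"D{j + 1:03d}" for j in range(p)]
    ids = [f"cmpd{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=names)

    # active columns: head of each block, spread across blocks
    active = [names[b * cfg.block_size] for b in range(cfg.n_active)]

    pathological: dict[str, str] = {}
    dup_sources: dict[str, str] = {}
    for k in range(cfg.n_constant):
        cname = f"CONST{k + 1}"
        frame[cname] = 1.0 + k
        pathological[cname] = "constant"
    for k in range(cfg.n_missing):
        cname = f"MISS{k + 1}"
        col = rng.standard_normal(n)
        col[int(rng.integers(n))] = np.nan
        frame[cname] = col
        pathological[cname] = "missing"
    for k in range(cfg.n_duplicate):
        # duplicate an active column: its univariate F is large, so the pair
        # reaches the collinearity rule, and the copy's name sorts after its
        # source, so the greedy tie-break drops the copy
        src = active[k % len(active)] if active else names[k % p]
        cname = f"DUP{k + 1}_{src}"
        frame[cname] = frame[src].to_numpy()
        pathological[cname] = "collinear"
        dup_sources[cname] = src

    meta = {c: DescriptorMeta(c, _SYNTH_CATEGORY) for c in frame.columns}
    beta = dict(zip(active, cfg.beta[1:]))
    truth = MatrixTruth(
        active=active,
        beta=beta,
        intercept=float(cfg.beta[0]),
        pathological=pathological,
        duplicate_sources=dup_sources,
    )
    return DescriptorMatrix(values=frame, meta=meta), truth


def gen_activity(
    X: DescriptorMatrix | pd.DataFrame,
    beta: Mapping[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
) -> pd.Series:
    """y = intercept + sum beta_j x_j + Normal(0, noise_sd²) noise."""
    frame = X.values if isinstance(X, DescriptorMatrix) else X
    missing = [c for c in beta if c not in frame.columns]
    if missing:
        raise ValueError(f"active columns not in X: {missing}")
    rng = np.random.default_rng(seed)
    y = np.full(len(frame), float(intercept))
    for c, b in beta.items():
        y = y + b * frame[c].to_numpy(dtype=float)
    y = y + rng.normal(0.0, noise_sd, size=len(frame))
    return pd.Series(y, index=frame.index, name="activity")


def population_r2(cfg: SynthConfig) -> float:
    """Closed-form population R² of the planted signal.

    Active columns sit in distinct equicorrelated blocks, so they are
    independent unit-variance Gaussians and the signal variance is simply
    the sum of squared coefficients.
    """
    var_signal = float(sum(b * b for b in cfg.beta[1:]))
    return var_signal / (var_signal + cfg.noise_sd**2)


def noise_sd_for_r2(beta: Sequence[float], target_r2: float) -> float:
    """Noise level giving the requested population R² for the planted signal
    (intercept excluded from ``beta``)."""
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    var_signal = float(sum(b * b for b in beta))
    return float(np.sqrt(var_signal * (1 - target_r2) / target_r2))


def gen_prescreen_case(
    seed: int = 0, n: int = 27, f_min: float = 1.0
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """A pathology-injected matrix with exact expected prescreen tags.

    Plants a constant column, a missing-value column, an exact duplicate of
    an informative column, and a column orthogonalized against the activity
    (univariate F identically 0 < f_min, hence tagged low_F — with
    univariate screening F = t², so a |t| < 0.1 violation is always absorbed
    by the F rule at the default thresholds).
    """
    cfg = SynthConfig(n_compounds=n, p_descriptors=10, n_active=2,
                      beta=(0.0, 3.0, -2.0), noise_sd=0.5,
                      n_constant=1, n_missing=1, n_duplicate=1, seed=seed)
    X, truth = gen_descriptor_matrix(cfg)
    y = gen_activity(X, truth.beta, cfg.noise_sd, seed=seed + 1, intercept=truth.intercept)
    frame = X.values.copy()
    rng = np.random.default_rng(seed + 2)
    raw = rng.standard_normal(n)
    yc = y.to_numpy() - y.to_numpy().mean()
    ortho = raw - raw.mean() - (raw @ yc) / (yc @ yc) * yc
    frame["ORTHO1"] = ortho
    expected = dict(truth.pathological)
    expected["ORTHO1"] = "low_F"
    return frame, y, expected


def _scenario_resource() -> dict:
    ref = resources.files("terpentox").joinpath("data/inhibition_scenario.json")
    with ref.open("r") as fh:
        return json.load(fh)


def load_inhibition_scenario() -> pd.DataFrame:
    """Packaged per-compound inhibition plateaus (fractions) at the four
    assay concentrations, emulating the study set's qualitative pattern.

    Returns a DataFrame indexed by compound id with one column per
    concentration (µM).
    """
    raw = _scenario_resource()
    frame = pd.DataFrame(raw["plateaus"]).T
    frame.columns = [float(c) for c in frame.columns]
    frame.index.name = "id"
    return frame.sort_index()


def gen_luminescence(
    cfg: LumSimConfig,
    conditions: Sequence[tuple[str, float, float]],
) -> pd.DataFrame:
    """Simulate RLU kinetics on the standard sampling grid.

    ``conditions`` holds (compound id, concentration in µM, I_max) triples;
    control: Gc(t) = gc0 exp(-k_c t) with lognormal noise; sample:
    Gs(t) = Gc(t) (1 - I_max (1 - exp(-t/tau))) with lognormal noise.
    Includes ``n_replicates`` control rows per concentration group.
    """
    for comp, conc, imax in conditions:
        if not (0.0 <= imax <= 1.5):
            raise ValueError(f"I_max {imax} for {comp!r} outside [0, 1.5]")
    rng = np.random.default_rng(cfg.seed)
    sigma = np.sqrt(np.log(1 + cfg.cv**2)) if cfg.cv > 0 else 0.0

    def noisy(mean: float) -> float:
        if sigma == 0:
            return mean
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        for t in TIME_GRID:
            gc = cfg.gc0 * np.exp(-cfg.k_c * t)
            rows.append(
                {
                    "condition": CONTROL,
                    "concentration_uM": 0.0,
                    "replicate": rep,
                    "time_min": t,
                    "rlu": noisy(gc),
                }
            )
    for comp, conc, imax in conditions:
        for rep in range(1, cfg.n_replicates + 1):
            for t in TIME_GRID:
                gc = cfg.gc0 * np.exp(-cfg.k_c * t)
                gs = gc * (1.0 - imax * (1.0 - np.exp(-t / cfg.tau)))
                rows.append(
                    {
                        "condition": comp,
                        "concentration_uM": conc,
                        "replicate": rep,
                        "time_min": t,
                        "rlu": noisy(gs),
                    }
                )
    return pd.DataFrame(rows)


def gen_assay_dataset(
    concentration: float,
    cfg: LumSimConfig | None = None,
    scenario: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Kinetics for every study compound at one assay concentration, using
    the packaged scenario plateaus by default."""
    scenario = load_inhibition_scenario() if scenario is None else scenario
    if concentration not in scenario.columns:
        raise ValueError(
            f"concentration {concentration} not in scenario "
            f"({list(scenario.columns)})"
        )
    cfg = LumSimConfig() if cfg is None else cfg
    conditions = [
        (comp, concentration, float(scenario.loc[comp, concentration]))
        for comp in scenario.index
    ]
    return gen_luminescence(cfg, conditions)
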