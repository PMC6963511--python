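"""Heuristic-method QSAR: descriptor pre-screening, best-subset multilinear
regression search, and validation statistics.

The pre-screen applies the classical elimination rules in order — missing
values, constant columns, uninformative univariate regressions (F below 1,
|t| below 0.1), and pairwise collinearity above 0.80 — then a stagewise beam
search grows multilinear models up to the descriptor cap (at least four
training compounds per descriptor), ranked by the training r². Model
validation covers the full statistics block: coefficient t-tests, residual
variance s², Fisher F, leave-one-out Q², and an external-test r².
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix


@dataclass(frozen=True)
class ScreeningConfig:
    f_min: float = 1.0
    t_min: float = 0.1
    alpha: float = 0.05
    r_pair_max: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.r_pair_max <= 1):
            raise ValueError("r_pair_max must be in (0, 1]")
        if self.f_min < 0 or self.t_min < 0 or self.alpha <= 0:
            raise ValueError("screening thresholds must be positive")


@dataclass(frozen=True)
class Elimination:
    name: str
    rule: str  # missing | constant | low_F | low_t | collinear
    partner: str | None = None  # the retained column, for collinear drops


@dataclass
class ScreenReport:
    surviving: list[str]
    eliminated: list[Elimination]

    @property
    def rules(self) -> dict[str, str]:
        """name -> rule tag, 'collinear(partner)' for collinearity drops."""
        out = {}
        for e in self.eliminated:
            out[e.name] = f"collinear({e.partner})" if e.rule == "collinear" else e.rule
        return out

    def check_partition(self, columns: Iterable[str]) -> bool:
        return set(self.surviving) | {e.name for e in self.eliminated} == set(columns)


@dataclass
class FittedModel:
    """A multilinear regression model with its validation statistics."""

    names: tuple[str, ...]
    intercept: float
    coefs: np.ndarray
    intercept_t: float
    tstats: np.ndarray
    se: np.ndarray
    r2: float
    s2: float
    F: float
    n: int
    y_mean: float
    q2: float | None = None
    r2_test: float | None = None
    outliers_removed: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.names)].to_numpy(dtype=float)
        return self.intercept + np.asarray(X, dtype=float) @ self.coefs

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.names),
            "intercept": self.intercept,
            "B": [float(b) for b in self.coefs],
            "t_intercept": self.intercept_t,
            "t": [float(t) for t in self.tstats],
            "r2_training": self.r2,
            "s2": self.s2,
            "F": self.F,
            "Q2": self.q2,
            "r2_test": self.r2_test,
            "n_training": self.n,
            "outliers_removed": list(self.outliers_removed),
        }


@dataclass
class SelectionResult:
    """Ranked candidate models plus the audit trail of the search."""

    models: list[FittedModel]
    best_per_size: dict[int, FittedModel]
    settings: dict
    audit: list[str] = field(default_factory=list)


def _as_frame(X: DescriptorMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.values
    return X


def _univariate_t(x: np.ndarray, y: np.ndarray) -> float:
    """t statistic of the slope of the one-descriptor regression y ~ x."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    b = sxy / sxx
    sse = syy - b * sxy
    if sse <= 0:
        return math.inf if b != 0 else 0.0
    s2 = sse / (n - 2)
    return b / math.sqrt(s2 / sxx)


def prescreen(
    X: DescriptorMatrix | pd.DataFrame,
    y: Sequence[float] | pd.Series,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> ScreenReport:
    """Apply the five elimination rules in order and report every decision.

    Note that with univariate screening F = t², so any column failing the
    |t| < t_min rule has F < t_min² and is already caught by the F rule at
    the default thresholds; the t rule only fires when f_min is lowered.
    """
    frame = _as_frame(X)
    yv = np.asarray(pd.Series(y).reindex(frame.index) if isinstance(y, pd.Series) else y,
                    dtype=float)
    if len(yv) != len(frame):
        raise ValueError("rows of X do not match y")
    if len(yv) < 3:
        raise ValueError("need at least 3 observations to screen")

    eliminated: list[Elimination] = []
    survivors: list[str] = []

    # (i) missing values, (ii) constant columns
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            eliminated.append(Elimination(name, "missing"))
        elif np.ptp(col) == 0.0:
            eliminated.append(Elimination(name, "constant"))
        else:
            survivors.append(name)

    # (iii) F < f_min and (iv) |t| < t_min from the one-descriptor regression
    kept: list[str] = []
    for name in survivors:
        t = _univariate_t(frame[name].to_numpy(dtype=float), yv)
        f = t * t
        if f < cfg.f_min:
            eliminated.append(Elimination(name, "low_F"))
        elif abs(t) < cfg.t_min:
            eliminated.append(Elimination(name, "low_t"))
        else:
            kept.append(name)
    survivors = kept

    # (v) pairwise collinearity: greedily drop the member less correlated
    # with the activity (ties keep the lexicographically first name)
    if len(survivors) >= 2:
        sub = frame[survivors].to_numpy(dtype=float)
        corr = np.corrcoef(sub, rowvar=False)
        ry = np.array(
            [abs(np.corrcoef(frame[c].to_numpy(dtype=float), yv)[0, 1]) for c in survivors]
        )
        alive = dict.fromkeys(survivors, True)
        pos = {name: k for k, name in enumerate(survivors)}
        while True:
            worst = None
            worst_r = cfg.r_pair_max
            names_alive = [c for c in survivors if alive[c]]
            for a, b in itertools.combinations(names_alive, 2):
                r = abs(corr[pos[a], pos[b]])
                if r > worst_r + 1e-15:
                    worst_r = r
                    worst = (a, b)
            if worst is None:
                break
            a, b = worst
            if ry[pos[a]] > ry[pos[b]] or (ry[pos[a]] == ry[pos[b]] and a < b):
                keep_col, drop_col = a, b
            else:
                keep_col, drop_col = b, a
            alive[drop_col] = False
            eliminated.append(Elimination(drop_col, "collinear", partner=keep_col))
        survivors = [c for c in survivors if alive[c]]

    return ScreenReport(surviving=survivors, eliminated=eliminated)


def fit_mlr(
    X_sub: pd.DataFrame | np.ndarray,
    y: Sequence[float] | pd.Series,
    names: Sequence[str] | None = None,
) -> FittedModel:
    """Ordinary least squares with intercept and the full statistics block.

    t statistics are B / SE(B) with SE from the residual variance
    s² = SSE/(n-p-1); r² = 1 - SSE/SST and F = (SSR/p) / s².
    """
    if isinstance(X_sub, pd.DataFrame):
        names = tuple(X_sub.columns) if names is None else tuple(names)
        Xv = X_sub.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X_sub, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = tuple(names) if names is not None else tuple(
            f"x{i + 1}" for i in range(Xv.shape[1])
        )
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    A = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("collinear subset: design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    sse = float(resid @ resid)
    sst = float(((yv - yv.mean()) ** 2).sum())
    s2 = sse / (n - p - 1)
    cov = np.linalg.inv(A.T @ A)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None) * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se_all > 0, beta / se_all, np.inf * np.sign(beta))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    ssr = sst - sse
    F = (ssr / p) / s2 if s2 > 0 else math.inf
    return FittedModel(
        names=names,
        intercept=float(beta[0]),
        coefs=beta[1:].copy(),
        intercept_t=float(t_all[0]),
        tstats=t_all[1:].copy(),
        se=se_all[1:].copy(),
        r2=float(r2),
        s2=float(s2),
        F=float(F),
        n=n,
        y_mean=float(yv.mean()),
    )


def loo_q2(X_sub: pd.DataFrame | np.ndarray, y: Sequence[float] | pd.Series) -> float:
    """Leave-one-out Q² = 1 - PRESS/SST.

    PRESS is the sum of squared deleted residuals — computed here through the
    exact hat-matrix identity e_(i) = e_i / (1 - h_ii), which is algebraically
    identical to refitting n times with one observation held out each time.
    """
    Xv = X_sub.to_numpy(dtype=float) if isinstance(X_sub, pd.DataFrame) else np.asarray(
        X_sub, dtype=float
    )
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < p + 3:
        raise ValueError(f"need n >= p + 3 for leave-one-out (n={n}, p={p})")
    sst = float(((yv - yv.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant activity: SST = 0")
    A = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("collinear subset: design matrix is rank deficient")
    Q, _ = np.linalg.qr(A)
    h = (Q * Q).sum(axis=1)
    if np.any(h > 1 - 1e-10):
        raise ValueError("a leave-one-out refit is rank deficient (leverage 1)")
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    press = float(((resid / (1.0 - h)) ** 2).sum())
    return 1.0 - press / sst


def max_descriptors(n_train: int, user_cap: int = 4) -> int:
    """Descriptor cap keeping at least four training compounds per descriptor."""
    if n_train < 5:
        raise ValueError("need at least 5 training compounds")
    return min(user_cap, n_train // 4)


class _SubsetEvaluator:
    """Fast r² evaluation of regression subsets from centered Gram matrices."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.n = len(y)
        self.Xc = X - X.mean(axis=0)
        self.yc = y - y.mean()
        self.G = self.Xc.T @ self.Xc
        self.g = self.Xc.T @ self.yc
        self.syy = float(self.yc @ self.yc)
        sd = np.sqrt(np.diag(self.G))
        with np.errstate(invalid="ignore", divide="ignore"):
            self.corr = self.G / np.outer(sd, sd)

    def r2(self, subset: tuple[int, ...]) -> float | None:
        idx = list(subset)
        G = self.G[np.ix_(idx, idx)]
        g = self.g[idx]
        try:
            beta = np.linalg.solve(G, g)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(beta)):
            return None
        # guard against numerically singular Gram blocks
        if np.linalg.cond(G) > 1e12:
            return None
        sse = self.syy - float(beta @ g)
        if self.syy <= 0:
            return None
        return 1.0 - sse / self.syy


def _rank_key(model: FittedModel) -> tuple:
    return (-model.r2, -model.F, len(model.names), model.names)


def _finalize(
    frame: pd.DataFrame,
    yv: np.ndarray,
    subsets: list[tuple[int, ...]],
    columns: list[str],
    compute_q2: bool,
    keep: int,
) -> list[FittedModel]:
    models = []
    for s in subsets:
        names = [columns[i] for i in s]
        try:
            m = fit_mlr(frame[names], yv)
        except ValueError:
            continue
        if compute_q2:
            try:
                m.q2 = loo_q2(frame[names], yv)
            except ValueError:
                m.q2 = None
        models.append(m)
    models.sort(key=_rank_key)
    return models[:keep]


def heuristic_search(
    X_screened: DescriptorMatrix | pd.DataFrame,
    y: Sequence[float] | pd.Series,
    max_desc: int,
    beam_width: int = 50,
    r_pair_max: float = 0.80,
    keep: int = 10,
    compute_q2: bool = True,
) -> SelectionResult:
    """Stagewise beam search over descriptor subsets.

    All one-descriptor models are ranked by r²; the top ``beam_width`` states
    are each extended by every descriptor whose pairwise correlation with the
    current members stays within ``r_pair_max``, keeping the best
    ``beam_width`` per size up to ``max_desc``. Returns the ranked models of
    the final size plus the best model of every size.
    """
    frame = _as_frame(X_screened)
    if frame.shape[1] == 0:
        raise ValueError("empty screened descriptor pool")
    if max_desc < 1:
        raise ValueError("max_desc must be >= 1")
    yv = np.asarray(pd.Series(y).reindex(frame.index) if isinstance(y, pd.Series) else y,
                    dtype=float)
    columns = list(frame.columns)
    ev = _SubsetEvaluator(frame.to_numpy(dtype=float), yv)
    audit: list[str] = []

    def top(states: dict[tuple[int, ...], float], width: int) -> list[tuple[int, ...]]:
        return sorted(
            states,
            key=lambda s: (-states[s], tuple(columns[i] for i in s)),
        )[:width]

    level: dict[tuple[int, ...], float] = {}
    for j in range(len(columns)):
        r2 = ev.r2((j,))
        if r2 is not None:
            level[(j,)] = r2
    if not level:
        raise ValueError("no usable single-descriptor model")
    beam = top(level, beam_width)
    audit.append(f"size 1: {len(level)} models, beam {len(beam)}")
    best_subsets: dict[int, tuple[int, ...]] = {1: beam[0]}
    final_level = {s: level[s] for s in beam}

    for size in range(2, max_desc + 1):
        nxt: dict[tuple[int, ...], float] = {}
        for s in beam:
            members = set(s)
            for j in range(len(columns)):
                if j in members:
                    continue
                if any(abs(ev.corr[j, i]) > r_pair_max for i in s):
                    continue
                cand = tuple(sorted(members | {j}))
                if cand in nxt:
                    continue
                r2 = ev.r2(cand)
                if r2 is not None:
                    nxt[cand] = r2
        if not nxt:
            audit.append(f"size {size}: no admissible extensions; stopping at size {size - 1}")
            break
        beam = top(nxt, beam_width)
        audit.append(f"size {size}: {len(nxt)} models, beam {len(beam)}")
        best_subsets[size] = beam[0]
        final_level = {s: nxt[s] for s in beam}

    models = _finalize(frame, yv, list(final_level), columns, compute_q2, keep)
    if not models:
        raise ValueError("no fit-able model found")
    best_per_size = {}
    for size, s in best_subsets.items():
        fitted = _finalize(frame, yv, [s], columns, compute_q2, 1)
        if fitted:
            best_per_size[size] = fitted[0]
    settings = {
        "method": "heuristic",
        "max_desc": max_desc,
        "beam_width": beam_width,
        "r_pair_max": r_pair_max,
    }
    return SelectionResult(models=models, best_per_size=best_per_size,
                           settings=settings, audit=audit)


def exhaustive_search(
    X_screened: DescriptorMatrix | pd.DataFrame,
    y: Sequence[float] | pd.Series,
    max_desc: int,
    limit: int = 2_000_000,
    keep: int = 10,
    compute_q2: bool = True,
) -> SelectionResult:
    """Evaluate every subset of size ``max_desc``; the exact best by r²."""
    frame = _as_frame(X_screened)
    if frame.shape[1] == 0:
        raise ValueError("empty screened descriptor pool")
    p = frame.shape[1]
    if max_desc < 1 or max_desc > p:
        raise ValueError(f"max_desc must be in [1, {p}]")
    n_subsets = math.comb(p, max_desc)
    if n_subsets > limit:
        raise ValueError(
            f"{n_subsets} subsets exceed the exhaustive limit {limit}; "
            f"use heuristic_search"
        )
    yv = np.asarray(pd.Series(y).reindex(frame.index) if isinstance(y, pd.Series) else y,
                    dtype=float)
    columns = list(frame.columns)
    ev = _SubsetEvaluator(frame.to_numpy(dtype=float), yv)
    scored: list[tuple[float, tuple[int, ...]]] = []
    for s in itertools.combinations(range(p), max_desc):
        r2 = ev.r2(s)
        if r2 is not None:
            scored.append((r2, s))
    if not scored:
        raise ValueError("no fit-able subset of the requested size")
    scored.sort(key=lambda t: (-t[0], tuple(columns[i] for i in t[1])))
    subsets = [s for _r, s in scored[: max(keep, 1)]]
    models = _finalize(frame, yv, subsets, columns, compute_q2, keep)
    best_per_size = {max_desc: models[0]} if models else {}
    return SelectionResult(
        models=models,
        best_per_size=best_per_size,
        settings={"method": "exhaustive", "max_desc": max_desc, "n_subsets": n_subsets},
        audit=[f"size {max_desc}: {n_subsets} subsets evaluated"],
    )


def flag_outliers(
    model: FittedModel,
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | pd.Series,
    z_thresh: float = 2.5,
) -> list:
    """Observations with |standardized residual| above ``z_thresh``.

    Standardization uses the internally studentized residual
    e_i / (s sqrt(1 - h_ii)). Returns row labels for DataFrame input,
    positions otherwise.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        Xv = X[list(model.names)].to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        labels = list(range(len(Xv)))
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    A = np.column_stack([np.ones(n), Xv])
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    Q, _ = np.linalg.qr(A)
    h = (Q * Q).sum(axis=1)
    s2 = float(resid @ resid) / (n - p - 1)
    if s2 <= 0:
        return []
    z = resid / np.sqrt(s2 * np.clip(1.0 - h, 1e-12, None))
    return [labels[i] for i in np.nonzero(np.abs(z) > z_thresh)[0]]


def evaluate_external(
    model: FittedModel,
    X_test: pd.DataFrame | np.ndarray,
    y_test: Sequence[float] | pd.Series,
    method: str = "pearson",
) -> float:
    """External-test r²: squared Pearson correlation between predictions and
    observations (default), or the predictive R² about the training mean
    (``method='predictive'``)."""
    yv = np.asarray(y_test, dtype=float)
    if len(yv) < 3:
        raise ValueError("need at least 3 test compounds")
    pred = model.predict(X_test)
    if method == "pearson":
        if np.std(pred) == 0 or np.std(yv) == 0:
            return 0.0
        return float(np.corrcoef(pred, yv)[0, 1] ** 2)
    if method == "predictive":
        denom = float(((yv - model.y_mean) ** 2).sum())
        if denom == 0:
            raise ValueError("degenerate test set: zero variance about training mean")
        return 1.0 - float(((yv - pred) ** 2).sum()) / denom
    raise ValueError("method must be 'pearson' or 'predictive'")


def split_train_test(
    compounds: Sequence[str],
    y: Sequence[float] | pd.Series,
    n_test: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Activity-stratified train/test split.

    Compounds are sorted by activity, cut into ``n_test`` contiguous strata,
    and one test compound is drawn per stratum (seeded), so the test set
    spans the activity range.
    """
    ids = list(compounds)
    yv = np.asarray(pd.Series(y).loc[ids] if isinstance(y, pd.Series) else y, dtype=float)
    if len(ids) != len(yv):
        raise ValueError("compounds and y must have the same length")
    if len(ids) < n_test + 5:
        raise ValueError(f"need at least n_test + 5 = {n_test + 5} compounds")
    order = sorted(range(len(ids)), key=lambda i: (yv[i], ids[i]))
    strata = np.array_split(np.array(order), n_test)
    rng = np.random.default_rng(seed)
    test_pos = sorted(int(rng.choice(s)) for s in strata)
    test = [ids[i] for i in test_pos]
    train = [c for c in ids if c not in set(test)]
    return train, test
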