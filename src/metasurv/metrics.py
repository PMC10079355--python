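"""Concordance index, Breslow baseline hazard and integrated Brier score.

The concordance index follows the literal ratio definition: comparable
pairs are (i, j) with Y_i < Y_j and the earlier patient uncensored; the
pair is concordant when the earlier patient has the higher predicted risk.
Pairs with exactly tied predicted risks are counted separately and excluded
from both numerator and denominator by default; ``ties="harrell"`` scores
them 1/2 for comparability with other software.

The Brier score at horizon t is the inverse-probability-of-censoring
weighted (IPCW) mean squared error between the predicted survival
probability S_hat(t|x_i) and the observed status, with weights from the
Kaplan-Meier estimate G of the censoring distribution (Graf convention:
G evaluated left-continuously at event times).  The integrated score
averages BS(t) over a time grid by the trapezoid rule, normalised by the
grid span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BaselineHazard:
    """Breslow step-function estimate of the cumulative baseline hazard."""

    event_times: np.ndarray  # sorted distinct event times
    cumulative_hazard: np.ndarray  # Lambda0 at each event time

    def cumhaz_at(self, times: np.ndarray) -> np.ndarray:
        """Lambda0(t), right-continuous, 0 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(times, dtype=float), "right")
        padded = np.r_[0.0, self.cumulative_hazard]
        return padded[idx]

    def survival(self, eta: np.ndarray, times: np.ndarray) -> np.ndarray:
        """S(t | x) = exp(-Lambda0(t) * e^eta); rows = patients, cols = times."""
        lam = self.cumhaz_at(times)
        return np.exp(-np.outer(np.exp(np.asarray(eta, dtype=float)), lam))


@dataclass
class MetricResult:
    c_index: float
    n_concordant: int
    n_discordant: int
    n_tied_risk: int
    n_comparable: int
    integrated_brier: float | None = None
    time_grid: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "c_index": float(self.c_index),
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "n_tied_risk": self.n_tied_risk,
            "n_comparable": self.n_comparable,
            "integrated_brier": None
            if self.integrated_brier is None
            else float(self.integrated_brier),
            "time_grid": None if self.time_grid is None else list(map(float, self.time_grid)),
        }


def concordance_index(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str = "exclude"
) -> MetricResult:
    """Fraction of comparable patient pairs ranked correctly by predicted risk.

    A pair (i, j) with Y_i < Y_j is comparable when patient i's event was
    observed; it is concordant when eta_i > eta_j (higher risk dies earlier).
    """
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = len(eta)
    if n < 2:
        raise ValueError("need at least 2 patients")
    ti, tj = time[:, None], time[None, :]
    comparable = (ti < tj) & event[:, None]
    ei, ej = eta[:, None], eta[None, :]
    conc = int((comparable & (ei > ej)).sum())
    disc = int((comparable & (ei < ej)).sum())
    tied = int((comparable & (ei == ej)).sum())
    denom = conc + disc
    if ties == "harrell":
        c = (conc + 0.5 * tied) / (denom + tied) if denom + tied else np.nan
    elif ties == "exclude":
        c = conc / denom if denom else np.nan
    else:
        raise ValueError(f"unknown tie rule {ties!r}")
    if conc + disc + tied == 0:
        warnings.warn("no comparable pairs: C-index undefined", stacklevel=2)
    return MetricResult(
        c_index=float(c) if not np.isnan(c) else np.nan,
        n_concordant=conc,
        n_discordant=disc,
        n_tied_risk=tied,
        n_comparable=conc + disc + tied,
    )


def breslow_baseline(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> BaselineHazard:
    """Breslow estimator: Lambda0(t) = sum_{t_i <= t} d_i / sum_{Y_j >= t_i} exp(eta_j)."""
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise ValueError("Breslow baseline requires at least one observed event")
    uniq = np.unique(time[event])
    incr = np.empty_like(uniq)
    exp_eta = np.exp(eta)
    for k, t in enumerate(uniq):
        d = int((event & (time == t)).sum())
        at_risk = exp_eta[time >= t].sum()
        incr[k] = d / at_risk
    return BaselineHazard(uniq, np.cumsum(incr))


def _km_censoring(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t) = P(censoring time > t).

    Returns step-function arrays (times, values); right-continuous.  Built on
    lifelines' Kaplan-Meier fitter with censoring as the event of interest.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - np.asarray(event))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _step_eval(xs: np.ndarray, ys: np.ndarray, t: np.ndarray, left: bool) -> np.ndarray:
    """Evaluate a right-continuous step function; ``left=True`` gives G(t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(xs, np.asarray(t, dtype=float), side) - 1
    padded = np.r_[1.0, ys]  # value 1 before the first observed time
    return padded[idx + 1]


def brier_scores(
    surv: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    time_grid: np.ndarray,
) -> np.ndarray:
    """IPCW Brier score BS(t) at each grid time.

    ``surv[i, k]`` is the predicted P(T_i > time_grid[k]).
    """
    surv = np.atleast_2d(np.asarray(surv, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    grid = np.asarray(time_grid, dtype=float)
    n = len(time)
    if surv.shape != (n, len(grid)):
        raise ValueError("survival matrix must be n_patients x n_grid_times")
    xs, ys = _km_censoring(time, event)
    G_at_grid = _step_eval(xs, ys, grid, left=False)
    G_before_Y = _step_eval(xs, ys, time, left=True)
    if np.any(G_at_grid <= 0):
        keep = G_at_grid > 0
        warnings.warn(
            "censoring survival reaches 0 inside the grid; truncating", stacklevel=2
        )
        grid, surv, G_at_grid = grid[keep], surv[:, keep], G_at_grid[keep]
    bs = np.empty(len(grid))
    for k, t in enumerate(grid):
        died = (time <= t) & event
        alive = time > t
        term_died = np.where(died, surv[:, k] ** 2 / np.where(G_before_Y > 0, G_before_Y, np.inf), 0.0)
        term_alive = np.where(alive, (1.0 - surv[:, k]) ** 2 / G_at_grid[k], 0.0)
        bs[k] = (term_died + term_alive).sum() / n
    return bs


def integrated_brier(
    surv: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    time_grid: np.ndarray,
) -> float:
    """Trapezoid-rule average of BS(t) over the grid, normalised by its span."""
    grid = np.asarray(time_grid, dtype=float)
    if len(grid) < 2:
        raise ValueError("need at least 2 grid points to integrate")
    bs = brier_scores(surv, time, event, grid)
    if len(bs) < len(grid):  # truncated inside brier_scores
        grid = grid[: len(bs)]
    span = grid[-1] - grid[0]
    if span <= 0:
        raise ValueError("degenerate time grid")
    return float(np.trapezoid(bs, grid) / span)


def default_time_grid(time: np.ndarray, n_points: int = 100) -> np.ndarray:
    """100 equally spaced points between the 5th and 95th percentile of times."""
    lo, hi = np.percentile(np.asarray(time, dtype=float), [5, 95])
    return np.linspace(lo, hi, n_points)


def bootstrap_ci(
    eta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the C-index, resampling patients."""
    eta = np.asarray(eta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    rng = np.random.default_rng(seed)
    n = len(eta)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c = concordance_index(eta[idx], time[idx], event[idx]).c_index
        if not np.isnan(c):
            stats.append(c)
    if not stats:
        return (np.nan, np.nan)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_predictions(
    eta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    baseline: BaselineHazard | None = None,
    time_grid: np.ndarray | None = None,
) -> MetricResult:
    """C-index, plus integrated Brier score when a baseline hazard is supplied."""
    res = concordance_index(eta, time, event)
    if baseline is not None:
        grid = default_time_grid(time) if time_grid is None else np.asarray(time_grid)
        surv = baseline.survival(eta, grid)
        res.integrated_brier = integrated_brier(surv, time, event, grid)
        res.time_grid = grid
    return res
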