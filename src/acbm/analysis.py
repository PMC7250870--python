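"""Post-processing of simulation time series.

Derived quantities: exponential-phase growth rate and doubling time, Monod
(µ vs C) parameter fits, starvation statistics, batch-phase detection, and
the Spearman correlation used to compare flux ratios with enzyme-activity
ratios.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_types import AVOGADRO


@dataclass
class ExponentialFit:
    mu_per_h: float
    doubling_time_h: Optional[float]
    window: tuple[float, float]  # time_min of first/last point used


@dataclass
class MonodFit:
    mu_max: float
    ks: float
    degenerate: bool = False


@dataclass
class StarvationStats:
    fraction: pd.DataFrame  # time_min, starved_fraction
    max_streak_min: pd.Series  # per agent id


def _biomass_column(ts: pd.DataFrame, species: Optional[str]) -> pd.Series:
    cols = [c for c in ts.columns if c.startswith("biomass_")]
    if species is not None:
        col = f"biomass_{species}_g_per_l"
        if col not in ts.columns:
            raise KeyError(col)
        return ts[col]
    if not cols:
        raise ValueError("no biomass columns in time series")
    return ts[cols].sum(axis=1)


def detect_log_window(t_h: np.ndarray, x: np.ndarray, tol: float = 0.1) -> tuple[int, int]:
    """Longest contiguous index span with near-constant log-slope.

    Local slopes of ln(x) between consecutive points must all stay within
    ``tol`` (relative) of the window's mean slope, and x must be positive
    throughout. Returns (i, j) inclusive; requires at least 3 points.
    """
    pos = x > 0
    logs = np.full_like(x, np.nan, dtype=float)
    logs[pos] = np.log(x[pos])
    slopes = np.diff(logs) / np.diff(t_h)
    n = len(slopes)
    best = None
    for i in range(n):
        if not np.isfinite(slopes[i]):
            continue
        for j in range(n, i + 1, -1):
            if best is not None and (j - i) <= (best[1] - best[0]):
                break
            win = slopes[i:j]
            if not np.isfinite(win).all():
                continue
            m = win.mean()
            scale = max(abs(m), 1e-12)
            if np.abs(win - m).max() <= tol * scale:
                best = (i, j)
                break
    if best is None:
        raise ValueError("no window with >= 3 positive points and stable log-slope")
    return best[0], best[1]  # slopes i..j-1 → points i..j


def fit_exponential(
    ts: pd.DataFrame,
    species: Optional[str] = None,
    window: Optional[tuple[float, float]] = None,
) -> ExponentialFit:
    """Least-squares fit of ln(biomass) vs time (hours) on the log window.

    Without an explicit ``window`` (in minutes), the longest span of
    near-constant local log-slope is auto-detected. A flat series fits
    µ = 0 and the doubling time is reported as ``None``.
    """
    t_min = ts["time_min"].to_numpy(dtype=float)
    x = _biomass_column(ts, species).to_numpy(dtype=float)
    if window is not None:
        sel = (t_min >= window[0]) & (t_min <= window[1])
        t_min, x = t_min[sel], x[sel]
        if len(x) < 3:
            raise ValueError("window holds fewer than 3 points")
        if (x <= 0).any():
            raise ValueError("non-positive biomass in window")
        i, j = 0, len(x) - 1
    else:
        i, j = detect_log_window(t_min / 60.0, x)
    t_h = t_min[i : j + 1] / 60.0
    xs = x[i : j + 1]
    if (xs <= 0).any():
        raise ValueError("non-positive biomass in window")
    mu = float(np.polyfit(t_h, np.log(xs), 1)[0])
    if abs(mu) < 1e-12:  # flat series: least-squares noise floor
        mu = 0.0
    doubling = math.log(2.0) / mu if mu > 0 else None
    return ExponentialFit(mu, doubling, (float(t_min[i]), float(t_min[j])))


def fit_monod(
    c: Sequence[float], mu: Sequence[float], tol: float = 1e-10
) -> MonodFit:
    """Nonlinear least squares of µ = µmax·C/(Ks + C).

    Initialised at µmax = max(µ), Ks = median(C). All-equal concentrations
    are degenerate and raise; all-equal rates mean no curvature information,
    reported as a degenerate fit with Ks pinned below min(C)/100.
    """
    c = np.asarray(c, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if len(c) < 3 or len(c) != len(mu):
        raise ValueError("need >= 3 (C, mu) pairs")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations equal: cannot fit Ks")
    if np.ptp(mu) <= 1e-12 * max(abs(mu).max(), 1.0):
        return MonodFit(float(mu.mean()), float(c.min() / 100.0), degenerate=True)
    p0 = (float(mu.max()), float(np.median(c)))
    popt, _ = optimize.curve_fit(
        lambda cc, mumax, ks: mumax * cc / (ks + cc),
        c,
        mu,
        p0=p0,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        maxfev=100000,
    )
    return MonodFit(float(popt[0]), float(popt[1]))


def monod_points(
    ts: pd.DataFrame,
    metabolite: str,
    mw_g_per_mol: float,
    min_conc_mol_per_l: float = 0.0,
    max_conc_mol_per_l: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Harvest (C in mol/l, mean µ) pairs from a run's recorded steps."""
    conc = ts[f"conc_{metabolite}_g_per_l"].to_numpy(dtype=float) / mw_g_per_mol
    mu = ts["mu_mean"].to_numpy(dtype=float)
    sel = (
        np.isfinite(mu)
        & (conc >= min_conc_mol_per_l)
        & (conc <= max_conc_mol_per_l)
    )
    return conc[sel], mu[sel]


# ---------------------------------------------------------------------------
# Starvation
# ---------------------------------------------------------------------------

def starvation_curve(
    ts: pd.DataFrame, agent_events: Optional[pd.DataFrame] = None
) -> StarvationStats:
    """Starved fraction over time and each agent's longest starved streak.

    A starved agent is one that failed to eat in a step. Streaks are
    consecutive starved steps while alive, in minutes; they need the
    per-agent event log (``record_agent_events=True`` at run time).
    """
    frac = ts[["time_min", "starved_fraction"]].dropna().reset_index(drop=True)
    if agent_events is None or agent_events.empty:
        return StarvationStats(frac, pd.Series(dtype=float))
    streaks: dict[int, float] = {}
    for aid, grp in agent_events.sort_values("time_min").groupby("agent_id"):
        times = grp["time_min"].to_numpy(dtype=float)
        ate = grp["ate"].to_numpy(dtype=bool)
        dt = float(np.diff(times).min()) if len(times) > 1 else float(times[0])
        best = cur = 0.0
        for a in ate:
            cur = 0.0 if a else cur + dt
            best = max(best, cur)
        streaks[int(aid)] = best
    return StarvationStats(frac, pd.Series(streaks, dtype=float))


# ---------------------------------------------------------------------------
# Batch phases
# ---------------------------------------------------------------------------

def detect_batch_phases(
    ts: pd.DataFrame, species: Optional[str] = None, smooth: int = 5
) -> list[tuple[str, float]]:
    """Onset times of the batch phases present, in order of appearance.

    Phases are classified from the (smoothed) biomass trajectory:

    * accelerating — growth has begun but a steady exponential rate is not
      yet established (the span before the constant-log-slope window);
    * log — the longest window of constant log-slope (rate µ_log);
    * decelerating — sustained instantaneous rate below 0.9·µ_log while
      biomass still rises;
    * stationary — |instantaneous rate| below 0.1·µ_log, sustained;
    * death — sustained biomass decline after the peak.

    Populations here reach full rate within a step or two (the model has no
    lag mechanism), so the accelerating span is brief by construction: the
    first recorded interval cannot yet exhibit an established constant rate
    and is classified as accelerating.
    """
    t_min = ts["time_min"].to_numpy(dtype=float)
    x = _biomass_column(ts, species).to_numpy(dtype=float)
    if smooth > 1 and len(x) > smooth:
        kernel = np.ones(smooth) / smooth
        xs = np.convolve(x, kernel, mode="same")
        xs[: smooth // 2] = x[: smooth // 2]
        xs[-(smooth // 2) :] = x[-(smooth // 2) :]
    else:
        xs = x.copy()
    t_h = t_min / 60.0
    i0, j0 = detect_log_window(t_h, xs)
    mu_log = float(
        np.polyfit(t_h[i0 : j0 + 1], np.log(np.maximum(xs[i0 : j0 + 1], 1e-300)), 1)[0]
    )
    if mu_log <= 0:
        raise ValueError("no growth: cannot classify batch phases")
    with np.errstate(divide="ignore", invalid="ignore"):
        inst = np.diff(np.log(np.maximum(xs, 1e-300))) / np.diff(t_h)

    log_onset_idx = max(i0, 1)  # the first interval is rate establishment
    phases: list[tuple[str, float]] = [("accelerating", float(t_min[0]))]
    phases.append(("log", float(t_min[log_onset_idx])))

    def _sustained(mask: np.ndarray, start: int, k: int = 3) -> Optional[int]:
        run = 0
        for i in range(start, len(mask)):
            run = run + 1 if mask[i] else 0
            if run >= min(k, len(mask) - start):
                return i - run + 1
        return None

    decel = _sustained((inst < 0.9 * mu_log) & (inst > 0.1 * mu_log), j0)
    stationary = _sustained(np.abs(inst) < 0.1 * mu_log, decel if decel is not None else j0)
    death = None
    if stationary is not None:
        peak = xs.max()
        death = _sustained((inst < 0) & (xs[1:] < 0.95 * peak), stationary)
    if decel is not None:
        phases.append(("decelerating", float(t_min[decel])))
    if stationary is not None and (decel is None or stationary > decel):
        phases.append(("stationary", float(t_min[stationary])))
    if death is not None and stationary is not None and death > stationary:
        phases.append(("death", float(t_min[death])))
    return phases


# ---------------------------------------------------------------------------
# Flux/activity correlation
# ---------------------------------------------------------------------------

def _spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def flux_activity_correlation(
    flux_ratios: Sequence[float], activity_ratios: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    For n > 10 the p-value uses the usual t approximation; for n ≤ 10 it is
    exact, by enumerating all permutations of one vector's ranks.
    """
    a = np.asarray(flux_ratios, dtype=float)
    b = np.asarray(activity_ratios, dtype=float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need paired vectors of length >= 5")
    n = len(a)
    rho = _spearman_rho(a, b)
    if n > 10:
        return rho, float(stats.spearmanr(a, b).pvalue)
    # exact permutation distribution of rho
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = (ra - ra.mean()) / np.sqrt(((ra - ra.mean()) ** 2).sum())
    rb_c = rb - rb.mean()
    denom = np.sqrt((rb_c**2).sum())
    if denom == 0 or not np.isfinite(rho):
        return rho, 1.0
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(ra @ rb_c[list(perm)]) / denom
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total
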