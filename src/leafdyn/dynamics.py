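"""Dynamic characteristics: growth rates over the sampling schedule and
growth-pattern model fitting.

Shape characteristics (LA, LP, EA, ED) are quantified by the relative
growth rate RGR = (ln W2 - ln W1) / (t2 - t1) after Hunt; colour
characteristics (G, NRI, DGCI, ExG, ExR) by the average changing rate
ACR = (X2 - X1) / (t2 - t1).  Rates are computed over a fixed interval
scheme on the scan schedule: consecutive 3-day periods P1, P2, ... or
non-overlapping 6-day periods P1', P2', ...; on the default DAT 20-44
schedule with the final (senescence-hit) period excluded this yields 7
three-day and 3 six-day data sets.

Blade-expansion trajectories are compared across candidate growth laws
(power a*t^b, exponential a*e^(b*t), sigmoidal logistic A/(1+e^(-k(t-t0))))
by nonlinear least squares, scored with R^2 and the SPSS-style
AIC = n*ln(RSS/n) + 2p, lower is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import BadInterval, BadSpacing, FitFailure, NonPositiveValue

log = logging.getLogger(__name__)

#: characteristics quantified by RGR (shape) and ACR (colour)
RGR_FEATURES = ["LA", "LP", "EA", "ED"]
ACR_FEATURES = ["G", "NRI", "DGCI", "ExG", "ExR"]

DYNAMIC_COLUMNS = [f"RGR_{f}" for f in RGR_FEATURES] + [f"ACR_{f}" for f in ACR_FEATURES]


def rgr(w1: float, w2: float, t1: float, t2: float) -> float:
    """Relative growth rate (per day): (ln W2 - ln W1) / (t2 - t1)."""
    if t2 <= t1:
        raise BadInterval(f"t2={t2} <= t1={t1}")
    if w1 <= 0 or w2 <= 0:
        raise NonPositiveValue(f"RGR undefined for W1={w1}, W2={w2}")
    return (np.log(w2) - np.log(w1)) / (t2 - t1)


def acr(x1: float, x2: float, t1: float, t2: float) -> float:
    """Average changing rate (units of X per day): (X2 - X1) / (t2 - t1)."""
    if t2 <= t1:
        raise BadInterval(f"t2={t2} <= t1={t1}")
    return (x2 - x1) / (t2 - t1)


@dataclass(frozen=True)
class IntervalScheme:
    """Ordered (t1, t2) measurement periods with one spacing."""

    spacing: int
    periods: tuple                # ((t1, t2), ...)
    labels: tuple                 # ("P1", ...) or ("P1'", ...)

    def __len__(self):
        return len(self.periods)

    def items(self):
        return zip(self.labels, self.periods)


def build_interval_scheme(
    schedule, spacing: int, drop_final: bool = True
) -> IntervalScheme:
    """Periods of one spacing on a scan schedule.

    3-day spacing gives consecutive pairs sharing endpoints; 6-day spacing
    gives non-overlapping pairs tiling the schedule.  ``drop_final``
    (default) removes the last period, modelling the loss of late
    observations to old-leaf senescence.
    """
    sched = list(schedule)
    if any(b <= a for a, b in zip(sched, sched[1:])):
        raise ValueError("schedule must be strictly increasing")
    step = sched[1] - sched[0] if len(sched) > 1 else None
    if step is None or spacing % step != 0:
        raise BadSpacing(f"spacing {spacing} not a multiple of schedule step {step}")
    stride = spacing // step
    pairs = []
    hop = 1 if stride == 1 else stride      # overlap endpoints only for base step
    i = 0
    while i + stride < len(sched):
        pairs.append((sched[i], sched[i + stride]))
        i += hop
    if drop_final and pairs:
        pairs = pairs[:-1]
    prime = "'" if stride > 1 else ""
    labels = tuple(f"P{j + 1}{prime}" for j in range(len(pairs)))
    return IntervalScheme(spacing=spacing, periods=tuple(pairs), labels=labels)


def dynamic_features(features: pd.DataFrame, scheme: IntervalScheme) -> pd.DataFrame:
    """Per-plant, per-period RGR/ACR table from a per-observation feature table.

    A cell is present only when both endpoint observations exist; RGR cells
    additionally require positive endpoint values (e.g. EA = 0 before the
    etiolation onset leaves RGR_EA missing, with the reason logged).
    """
    key = ["plant_id", "treatment", "year", "leaf_position"]
    rows = []
    for group_key, grp in features.groupby(key, sort=True):
        by_dat = grp.set_index("dat")
        for label, (t1, t2) in scheme.items():
            if t1 not in by_dat.index or t2 not in by_dat.index:
                continue
            a, b = by_dat.loc[t1], by_dat.loc[t2]
            row = dict(zip(key, group_key))
            row.update({"period": label, "t1": t1, "t2": t2})
            for feat in RGR_FEATURES:
                w1, w2 = a.get(feat), b.get(feat)
                if w1 is None or w2 is None or pd.isna(w1) or pd.isna(w2):
                    row[f"RGR_{feat}"] = np.nan
                elif w1 <= 0 or w2 <= 0:
                    row[f"RGR_{feat}"] = np.nan
                    log.info("RGR_%s missing for %s %s: non-positive endpoint",
                             feat, group_key, label)
                else:
                    row[f"RGR_{feat}"] = rgr(w1, w2, t1, t2)
            for feat in ACR_FEATURES:
                x1, x2 = a.get(feat), b.get(feat)
                if x1 is None or x2 is None or pd.isna(x1) or pd.isna(x2):
                    row[f"ACR_{feat}"] = np.nan
                else:
                    row[f"ACR_{feat}"] = acr(x1, x2, t1, t2)
            rows.append(row)
    cols = key + ["period", "t1", "t2"] + DYNAMIC_COLUMNS
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# growth-pattern fitting
# ---------------------------------------------------------------------------

GROWTH_MODELS = ("power", "exponential", "logistic")

_N_PARAMS = {"power": 2, "exponential": 2, "logistic": 3}


def _power(t, a, b):
    return a * np.power(t, b)


def _exponential(t, a, b):
    return a * np.exp(b * t)


def _logistic(t, A, k, t0):
    return A / (1.0 + np.exp(-k * (t - t0)))


_MODEL_FUNCS = {"power": _power, "exponential": _exponential, "logistic": _logistic}


@dataclass
class GrowthModelFit:
    """One model family fitted to one trajectory."""

    model: str
    params: tuple
    rss: float
    r2: float
    aic: float
    n_points: int
    converged: bool = True
    start: tuple = ()


def _starts(model: str, t: np.ndarray, y: np.ndarray):
    """Documented multi-start grid; log-linear seeds plus coarse fallbacks."""
    if model == "power":
        with np.errstate(all="ignore"):
            b, loga = np.polyfit(np.log(t), np.log(y), 1)
        yield (np.exp(loga), b)
        yield (max(y.mean(), 1e-6), 1.0)
    elif model == "exponential":
        with np.errstate(all="ignore"):
            b, loga = np.polyfit(t, np.log(y), 1)
        yield (np.exp(loga), b)
        yield (max(y[0], 1e-6), 0.0)
    else:  # logistic
        a0 = max(y.max(), 1e-6)
        t_mid = t[np.argmin(np.abs(y - a0 / 2.0))]
        for a in (a0, 1.5 * a0):
            for k in (0.1, 0.3, 0.8, 1.5):
                for t0 in (t_mid, np.median(t)):
                    yield (a, k, t0)


def fit_growth_model(times, values, model: str, use_aicc: bool = False) -> GrowthModelFit:
    """Nonlinear least-squares fit of one growth law to one trajectory.

    Requires >= n_params + 1 points; power/exponential additionally need
    positive values (they are seeded from log-linear regression).  All
    starting points of the documented grid are tried and the best-RSS
    convergent fit wins.  AIC = n*ln(RSS/n) + 2p; RSS = 0 reports -inf.
    With ``use_aicc`` the small-sample correction 2p(p+1)/(n-p-1) is added.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    p = _N_PARAMS[model]
    if t.size != y.size or t.size < p + 1:
        raise ValueError(f"{model} needs at least {p + 1} points")
    if model in ("power", "exponential") and np.any(y <= 0):
        raise ValueError(f"{model} model requires positive values")
    func = _MODEL_FUNCS[model]

    best = None
    for start in _starts(model, t, y):
        try:
            with np.errstate(all="ignore"):
                popt, _ = curve_fit(func, t, y, p0=start, maxfev=10000)
                rss = float(((y - func(t, *popt)) ** 2).sum())
        except (RuntimeError, TypeError, ValueError):
            continue
        if not np.isfinite(rss):
            continue
        if best is None or rss < best[1]:
            best = (tuple(popt), rss, tuple(start))
    if best is None:
        raise FitFailure(f"{model} fit failed from all starting points (n={t.size})")

    popt, rss, start = best
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-300 else 0.0)
    n = t.size
    if rss <= 0:
        aic = -np.inf
    else:
        aic = n * np.log(rss / n) + 2 * p
        if use_aicc:
            aic += 2 * p * (p + 1) / (n - p - 1)
    return GrowthModelFit(model=model, params=popt, rss=rss, r2=r2, aic=float(aic),
                          n_points=n, start=start)


def select_growth_model(fits: list[GrowthModelFit]) -> GrowthModelFit:
    """Minimal-AIC fit; AIC ties break toward fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, _N_PARAMS[f.model]))


def fit_report(features: pd.DataFrame, models=GROWTH_MODELS) -> pd.DataFrame:
    """Growth-law comparison per treatment x leaf position for LA and LP.

    Fits the replicate-mean trajectory of each characteristic, mirroring
    the growth-pattern-fitness step of the analysis.
    """
    rows = []
    for (treatment, position), grp in features.groupby(
        ["treatment", "leaf_position"], sort=True
    ):
        mean_traj = grp.groupby("dat")[["LA", "LP"]].mean()
        for char in ("LA", "LP"):
            y = mean_traj[char].dropna()
            if len(y) < 4:
                continue
            for model in models:
                try:
                    f = fit_growth_model(y.index.values, y.values, model)
                except (ValueError, FitFailure) as exc:
                    log.warning("fit %s/%s/%s failed: %s", treatment, position,
                                model, exc)
                    continue
                rows.append({
                    "treatment": treatment, "leaf_position": position,
                    "characteristic": char, "model": model,
                    "params": ";".join(f"{v:.6g}" for v in f.params),
                    "rss": f.rss, "r2": f.r2, "aic": f.aic, "n_points": f.n_points,
                })
    return pd.DataFrame(rows)
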