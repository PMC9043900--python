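"""Growth monitoring: GR/RGR metrics and Tukey-HSD stress detection.

Per-plant biomass predictions taken every 8 h are smoothed with a
backwards-looking moving average (window 3), differenced into growth rate
GR = (m_t - m_{t-1}) / dt and relative growth rate RGR = GR / m_t (units
(8 h)^-1).  At every timepoint, treatment means are compared with Tukey's
honestly-significant-difference test (studentized range, pooled
within-group variance) at alpha = 0.05.  Because GR/RGR fluctuate enough
to produce sporadic single-timepoint separations, a stress response is
declared only on the stricter criterion of two consecutive significant
timepoints ("double"); first separation ("single") is used for the
smoother biomass series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._studentized_range import studentized_range_sf

ALPHA_DEFAULT = 0.05
METRICS = ("biomass", "GR", "RGR")


@dataclass
class GrowthSeries:
    """One plant's uniformly sampled mass trajectory."""

    plant_id: str
    treatment_label: str
    times: np.ndarray  # timepoint indices or times, uniform spacing
    mass_g: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if len(t) != len(self.mass_g):
            raise ValueError("times and mass must align")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ValueError("times must be strictly increasing with uniform spacing")


@dataclass
class SeparationResult:
    """Per-timepoint Tukey separation between one treatment pair."""

    pair: tuple[str, str]
    times: np.ndarray
    p_values: np.ndarray
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> np.ndarray:
        return self.p_values <= self.alpha


def moving_average(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Backwards-looking moving average; the first window-1 positions are
    dropped, so smoothed[i] aligns with original index i + window - 1."""
    series = np.asarray(series, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(series) < window:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.ones(window) / window
    return np.convolve(series, kernel, mode="valid")


def growth_rate(smoothed: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """GR[t] = (m_t - m_{t-1}) / dt in grams per dt (default dt = one 8-h step)."""
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(smoothed) < 2:
        raise ValueError("need at least two smoothed points")
    return np.diff(smoothed) / dt


def relative_growth_rate(gr: np.ndarray, smoothed: np.ndarray) -> np.ndarray:
    """RGR[t] = GR[t] / m_t with m_t the current smoothed mass (units 1/dt).

    ``smoothed`` must be the series GR was computed from; its first element
    (the t-1 boundary) is dropped to align denominators with GR.
    """
    gr = np.asarray(gr, dtype=np.float64)
    smoothed = np.asarray(smoothed, dtype=np.float64)
    m_t = smoothed[1:]
    if len(m_t) != len(gr):
        raise ValueError("GR and smoothed series misaligned")
    if np.any(m_t <= 0):
        raise ValueError("RGR requires positive mass")
    return gr / m_t


def growth_metrics(
    df: pd.DataFrame,
    window: int = 3,
    dt: float = 1.0,
    value_col: str = "mass_g",
) -> pd.DataFrame:
    """Long-format per-plant metrics from a (plant_id, treatment, timepoint,
    mass) table.  Boundary timepoints lost to smoothing/differencing are
    dropped; ``biomass`` is the smoothed series."""
    required = {"plant_id", "treatment", "timepoint", value_col}
    if not required.issubset(df.columns):
        raise ValueError(f"input needs columns {sorted(required)}")
    rows = []
    for pid, g in df.sort_values("timepoint").groupby("plant_id"):
        t = g["timepoint"].to_numpy()
        m = g[value_col].to_numpy(dtype=np.float64)
        treatment = g["treatment"].iloc[0]
        ma = moving_average(m, window)
        t_ma = t[window - 1 :]
        gr = growth_rate(ma, dt)
        rgr = relative_growth_rate(gr, ma)
        t_gr = t_ma[1:]
        for tt, v in zip(t_ma, ma):
            rows.append((pid, treatment, tt, "biomass", v))
        for tt, v in zip(t_gr, gr):
            rows.append((pid, treatment, tt, "GR", v))
        for tt, v in zip(t_gr, rgr):
            rows.append((pid, treatment, tt, "RGR", v))
    return pd.DataFrame(rows, columns=["plant_id", "treatment", "timepoint", "metric", "value"])


# ---------------------------------------------------------------------------
# Tukey HSD separation
# ---------------------------------------------------------------------------

def tukey_pairwise(groups: dict[str, np.ndarray], alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """All-pairs Tukey HSD p-values at one timepoint.

    Returns a symmetric DataFrame indexed by group label with diagonal 1.
    Degenerate pooled variance (all values identical within every group)
    is resolved by direct comparison of means: equal means give p = 1,
    distinct means p = 0.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    for k, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    p = np.eye(len(labels))
    k = len(labels)
    ns = np.array([len(a) for a in arrays])
    nu = float((ns - 1).sum())
    pooled_var = float(sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / nu)
    means = [a.mean() for a in arrays]
    for i, j in itertools.combinations(range(k), 2):
        if pooled_var == 0.0:
            p[i, j] = p[j, i] = 1.0 if means[i] == means[j] else 0.0
            continue
        se = np.sqrt(pooled_var / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        p[i, j] = p[j, i] = studentized_range_sf(q, k, nu)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=labels, columns=labels)


def separation_over_time(
    metric_df: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    metric: str | None = None,
) -> dict[tuple[str, str], SeparationResult]:
    """Run Tukey HSD per timepoint; build per-pair boolean separation series.

    ``metric_df`` is long format (plant_id, treatment, timepoint, value),
    optionally with a ``metric`` column filtered by ``metric``.  Every
    treatment must cover the same timepoints; plants missing a value at a
    timepoint are excluded from that timepoint's groups.
    """
    df = metric_df
    if metric is not None:
        df = df[df["metric"] == metric]
    df = df.dropna(subset=["value"])
    treatments = sorted(df["treatment"].unique())
    if len(treatments) < 2:
        raise ValueError("need at least two treatments")
    tp_sets = {tr: set(df.loc[df["treatment"] == tr, "timepoint"]) for tr in treatments}
    common = set.intersection(*tp_sets.values())
    if any(tp_sets[tr] != common for tr in treatments):
        raise ValueError("treatments cover different timepoints")
    times = np.array(sorted(common))
    pairs = list(itertools.combinations(treatments, 2))
    pmat = {pair: np.ones(len(times)) for pair in pairs}
    for ti, t in enumerate(times):
        at_t = df[df["timepoint"] == t]
        groups = {
            tr: at_t.loc[at_t["treatment"] == tr, "value"].to_numpy() for tr in treatments
        }
        ptab = tukey_pairwise(groups, alpha=alpha)
        for a, b in pairs:
            pmat[(a, b)][ti] = ptab.loc[a, b]
    return {
        pair: SeparationResult(pair=pair, times=times, p_values=pmat[pair], alpha=alpha)
        for pair in pairs
    }


def detect_response(sep: SeparationResult, criterion: str = "double"):
    """First time the separation criterion holds, or None.

    ``single``: first significant timepoint.  ``double``: first timepoint t
    such that both t-1 and t are significant (reported at t, the moment
    the criterion is satisfied).
    """
    sig = sep.significant
    if criterion == "single":
        idx = np.flatnonzero(sig)
        return sep.times[idx[0]] if idx.size else None
    if criterion == "double":
        idx = np.flatnonzero(sig[1:] & sig[:-1])
        return sep.times[idx[0] + 1] if idx.size else None
    raise ValueError("criterion must be 'single' or 'double'")


def response_time(detection_time_days: float, stress_day: float) -> float:
    """Days from stress onset to detection; detection before onset is an
    error (it signals a false positive the caller must handle)."""
    if detection_time_days < stress_day:
        raise ValueError("detection precedes stress onset (false positive)")
    return detection_time_days - stress_day


def timepoints_to_days(timepoints: np.ndarray, dt_hours: float = 8.0) -> np.ndarray:
    return np.asarray(timepoints, dtype=np.float64) * dt_hours / 24.0


def plot_metric_means(
    metric_df: pd.DataFrame,
    metric: str,
    dt_hours: float = 8.0,
    ax=None,
):
    """Mean +/- 95% CI per treatment over time (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    df = metric_df[metric_df["metric"] == metric] if "metric" in metric_df else metric_df
    if ax is None:
        _, ax = plt.subplots()
    for tr, g in df.groupby("treatment"):
        agg = g.groupby("timepoint")["value"].agg(["mean", "sem", "count"])
        days = timepoints_to_days(agg.index.to_numpy(), dt_hours)
        ci = 1.96 * agg["sem"]
        ax.plot(days, agg["mean"], label=str(tr))
        ax.fill_between(days, agg["mean"] - ci, agg["mean"] + ci, alpha=0.25)
    unit = {"biomass": "g", "GR": "g (8 h)$^{-1}$", "RGR": "(8 h)$^{-1}$"}.get(metric, "")
    ax.set_xlabel("days")
    ax.set_ylabel(f"{metric} [{unit}]")
    ax.legend(title="treatment")
    return ax
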