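"""Rates, yields and consortium performance metrics from batch trajectories.

Six performance metrics summarize a batch culture: final biomass titer, total
glucose catabolized, biomass per glucose consumed, biomass per proton
accumulated, final by-product (organic acid) level, and specific growth rate
over the exponential window.  They apply equally to simulated trajectories and
to observation tables produced by :mod:`crossfeed.synthdata` or read from CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acidbase import AcidSpec, MediumSpec, charge_imbalance
from .simulation import GLUCOSE_MOLAR_MASS, Trajectory

__all__ = [
    "GrowthRateEstimate",
    "PerformanceReport",
    "estimate_growth_rate",
    "performance_report",
    "protons_accumulated",
    "compare_reports",
    "reconstruct_proton_load",
]

DEFAULT_VOLUME_L = 0.1  # 100-mL experimental batch cultures


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu: float  # 1/h
    window: tuple[float, float]  # h
    n_points: int
    r_squared: float
    low_confidence: bool


def _window_stats(t: np.ndarray, y: np.ndarray):
    """Prefix sums enabling O(1) slope/R^2 for any contiguous window."""
    z = np.zeros(1)
    return (
        np.concatenate([z, np.cumsum(t)]),
        np.concatenate([z, np.cumsum(y)]),
        np.concatenate([z, np.cumsum(t * t)]),
        np.concatenate([z, np.cumsum(y * y)]),
        np.concatenate([z, np.cumsum(t * y)]),
    )


def estimate_growth_rate(
    time: np.ndarray,
    biomass: np.ndarray,
    r2_threshold: float = 0.98,
    min_points: int = 4,
) -> GrowthRateEstimate:
    """Log-linear growth rate over a detected exponential window.

    The window is the largest contiguous set of points (minimum
    ``min_points``) whose ln(biomass)-vs-time fit reaches ``r2_threshold``;
    earlier windows win ties.  If no window qualifies, the best-R^2 window is
    returned flagged low-confidence.  The estimate is invariant to uniform
    scaling of biomass (only the log-slope matters).
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(biomass, dtype=float)
    keep = x > 0
    t, x = t[keep], x[keep]
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} positive-biomass points")
    y = np.log(x)
    st, sy, stt, syy, sty = _window_stats(t, y)

    def fit(i: int, j: int) -> tuple[float, float]:
        """slope and R^2 for points i..j inclusive."""
        n = j - i + 1
        s_t = st[j + 1] - st[i]
        s_y = sy[j + 1] - sy[i]
        s_tt = stt[j + 1] - stt[i]
        s_yy = syy[j + 1] - syy[i]
        s_ty = sty[j + 1] - sty[i]
        var_t = s_tt - s_t * s_t / n
        cov = s_ty - s_t * s_y / n
        var_y = s_yy - s_y * s_y / n
        if var_t <= 0:
            return math.nan, -math.inf
        slope = cov / var_t
        if var_y <= 1e-300:
            return slope, 1.0  # flat data fit exactly by a flat line
        r2 = 1.0 - max(var_y - cov * cov / var_t, 0.0) / var_y
        return slope, r2

    m = t.size
    best = None  # (length, -start, slope, r2, i, j) maximized
    fallback = None  # best r2 of any window
    for i in range(m):
        for j in range(i + min_points - 1, m):
            slope, r2 = fit(i, j)
            length = j - i + 1
            if r2 >= r2_threshold:
                key = (length, -i)
                if best is None or key > best[0]:
                    best = (key, slope, r2, i, j)
            fkey = (r2, length, -i)
            if fallback is None or fkey > fallback[0]:
                fallback = (fkey, slope, r2, i, j)

    low_confidence = best is None
    _, slope, r2, i, j = best if best is not None else fallback
    return GrowthRateEstimate(
        mu=float(slope),
        window=(float(t[i]), float(t[j])),
        n_points=j - i + 1,
        r_squared=float(r2),
        low_confidence=low_confidence,
    )


@dataclass(frozen=True)
class PerformanceReport:
    final_biomass: float  # g cdw/L
    glucose_consumed: float  # mmol per culture
    biomass_per_glucose: float | None  # g cdw / g glucose
    biomass_per_proton: float | None  # g cdw / mol H+
    byproduct_final: float  # mM organic acid
    specific_growth_rate: float  # 1/h
    growth_window: tuple[float, float]  # h
    growth_r_squared: float
    low_confidence_mu: bool

    def as_dict(self) -> dict:
        return asdict(self)

    _METRICS = (
        "final_biomass", "glucose_consumed", "biomass_per_glucose",
        "biomass_per_proton", "byproduct_final", "specific_growth_rate",
    )


def protons_accumulated(trajectory: Trajectory) -> float:
    """Total H+ delivered to the medium over the batch (mol/L).

    Counts the biomass-linked strong-acid equivalents plus the protons
    released by organic-acid dissociation (the change in the dissociated
    fraction A- at the prevailing pH).  Consumed acid therefore credits the
    inventory back, so a consortium that keeps its by-product low accumulates
    fewer protons per unit biomass than an acid-accumulating culture.
    """
    load = float(trajectory.proton_load[-1] - trajectory.proton_load[0])
    acid = trajectory.scenario.acid if trajectory.scenario is not None else None
    if acid is None:
        return load
    a_frac_end = 1.0 - 1.0 / (1.0 + 10.0 ** (trajectory.pH[-1] - acid.pKa))
    a_frac_0 = 1.0 - 1.0 / (1.0 + 10.0 ** (trajectory.pH[0] - acid.pKa))
    d_anion = (
        trajectory.acid_total[-1] * a_frac_end - trajectory.acid_total[0] * a_frac_0
    ) * 1e-3
    return load + float(d_anion)


def _doubling_indices(x: np.ndarray) -> np.ndarray:
    """Indices subsampling a dense trajectory once per biomass doubling."""
    idx = [0]
    ref = x[0]
    for i in range(1, len(x)):
        if ref > 0 and x[i] >= 2.0 * ref:
            idx.append(i)
            ref = x[i]
    if idx[-1] != len(x) - 1:
        idx.append(len(x) - 1)
    return np.array(idx)


def performance_report(
    trajectory: Trajectory,
    volume_L: float = DEFAULT_VOLUME_L,
) -> PerformanceReport:
    """Compute the six performance metrics from a complete batch trajectory.

    The growth rate is estimated on a once-per-doubling subsample of the
    trajectory, mirroring how batch cultures are sampled; on a dense solver
    grid this keeps the exponential-window search from locking onto the long,
    smooth stationary phase.
    """
    x = trajectory.total_biomass
    dx = float(x[-1] - x[0])
    dglc_mM = float(trajectory.glucose[0] - trajectory.glucose[-1])
    dglc_g_per_L = dglc_mM * GLUCOSE_MOLAR_MASS / 1000.0
    load = protons_accumulated(trajectory)

    if dx > 0 and x[0] > 0:
        sub = _doubling_indices(x)
        if len(sub) >= 4:
            est = estimate_growth_rate(trajectory.time[sub], x[sub])
        else:
            est = estimate_growth_rate(trajectory.time, x)
        mu, window, r2, lowc = est.mu, est.window, est.r_squared, est.low_confidence
    else:
        mu, window, r2, lowc = 0.0, (0.0, 0.0), 1.0, False

    return PerformanceReport(
        final_biomass=float(x[-1]),
        glucose_consumed=dglc_mM * volume_L,
        biomass_per_glucose=(dx / dglc_g_per_L) if dglc_g_per_L > 0 else None,
        biomass_per_proton=(dx / load) if load > 0 else None,
        byproduct_final=float(trajectory.acid_total[-1]),
        specific_growth_rate=mu,
        growth_window=window,
        growth_r_squared=r2,
        low_confidence_mu=lowc,
    )


def compare_reports(
    a: Sequence[PerformanceReport] | PerformanceReport,
    b: Sequence[PerformanceReport] | PerformanceReport,
) -> pd.DataFrame:
    """Percent differences and Welch (unequal-variance) t-tests per metric.

    ``a``/``b`` are replicate sets (or single reports, in which case no test
    is performed).  Percent difference is (mean_a - mean_b)/mean_b * 100.
    """
    la = [a] if isinstance(a, PerformanceReport) else list(a)
    lb = [b] if isinstance(b, PerformanceReport) else list(b)
    rows = []
    for metric in PerformanceReport._METRICS:
        va = np.array([getattr(r, metric) for r in la if getattr(r, metric) is not None],
                      dtype=float)
        vb = np.array([getattr(r, metric) for r in lb if getattr(r, metric) is not None],
                      dtype=float)
        if va.size == 0 or vb.size == 0:
            rows.append({"metric": metric, "mean_a": np.nan, "mean_b": np.nan,
                         "percent_diff": np.nan, "t_stat": np.nan, "p_value": np.nan})
            continue
        ma, mb = va.mean(), vb.mean()
        pct = (ma - mb) / mb * 100.0 if mb != 0 else np.nan
        if va.size >= 2 and vb.size >= 2:
            if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and np.isclose(ma, mb):
                tstat, pval = 0.0, 1.0
            else:
                tstat, pval = stats.ttest_ind(va, vb, equal_var=False)
        else:
            tstat, pval = np.nan, np.nan
        rows.append({"metric": metric, "mean_a": ma, "mean_b": mb,
                     "percent_diff": pct, "t_stat": float(tstat),
                     "p_value": float(pval)})
    return pd.DataFrame(rows)


def reconstruct_proton_load(
    pH: np.ndarray,
    acid_totals_mM: np.ndarray,
    acid: AcidSpec,
    medium: MediumSpec,
) -> np.ndarray:
    """Invert the charge balance at each measured pH to recover the cumulative
    strong-acid-equivalent proton load (mol/L).

    This is the observed-data backend for the biomass-per-proton metric; it is
    model-dependent (it assumes the same buffer description used forward).
    """
    if medium.fixed_cation_offset is None:
        medium = medium.initialize(acids=[(acid, medium.acid_0)])
    out = np.empty(len(pH), dtype=float)
    for k, (ph, tot) in enumerate(zip(pH, acid_totals_mM)):
        out[k] = charge_imbalance(float(ph), 0.0, [(acid, float(tot))], medium)
    return out
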