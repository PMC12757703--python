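"""Non-compartmental analysis and model-qualification statistics.

NCA conventions: Cmax/Tmax with an earliest-maximum tie-break; linear
trapezoidal AUC; terminal rate constant λz from a log-linear fit over the
adjusted-R²-maximizing terminal point subset (at least three positive
post-peak points, the peak itself excluded); AUC_inf = AUC_last + C_last/λz;
t½ = ln2/λz.

Qualification statistics follow the standard PBPK verification toolkit:
R ratio = observed/predicted (acceptable in [0.5, 2.0], the two-fold
criterion), fold error = predicted/observed, average fold error
AFE = 10^(mean log10 fold error), and RMSE/MAE between paired simulated and
observed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTimeProfile",
    "PKParameters",
    "EvaluationMetrics",
    "cmax_tmax",
    "auc_trapezoid",
    "lambda_z",
    "auc_inf",
    "nca",
    "r_ratio",
    "fold_error",
    "afe",
    "rmse_mae",
    "two_fold_check",
    "read_profile_csv",
    "round_sig",
]


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """A sampled plasma concentration–time profile (h, ng/mL)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.size != c.size or t.size < 2:
            raise ValueError("profile needs >= 2 matching time/concentration points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PKParameters:
    cmax: float  # ng/mL
    tmax: float  # h
    auc_last: float  # ng*h/mL, to the last sampled time
    auc_inf: float | None = None  # ng*h/mL
    lambda_z: float | None = None  # 1/h
    t_half: float | None = None  # h
    auc_window: float | None = None  # ng*h/mL over a scenario-defined window
    window_end: float | None = None  # h

    def as_dict(self) -> dict[str, float | None]:
        return {
            "cmax": self.cmax,
            "tmax": self.tmax,
            "auc_last": self.auc_last,
            "auc_inf": self.auc_inf,
            "lambda_z": self.lambda_z,
            "t_half": self.t_half,
            "auc_window": self.auc_window,
            "window_end": self.window_end,
        }


@dataclass(frozen=True)
class EvaluationMetrics:
    r_ratio: float
    fold_error: float
    within_two_fold: bool
    afe: float | None = None
    rmse: float | None = None
    mae: float | None = None


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum concentration and its earliest time of occurrence."""
    i = int(np.argmax(profile.concentrations))  # argmax takes the first maximum
    return float(profile.concentrations[i]), float(profile.times[i])


def auc_trapezoid(profile: ConcentrationTimeProfile, t_end: float | None = None) -> float:
    """Linear trapezoidal AUC from the first sample to ``t_end``.

    ``t_end`` may fall between samples (linear interpolation); it must lie
    within the sampled range.
    """
    t, c = profile.times, profile.concentrations
    if t_end is None:
        t_end = float(t[-1])
    if t_end < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ValueError(
            f"t_end {t_end} outside sampled range [{t[0]}, {t[-1]}]"
        )
    t_end = min(max(t_end, float(t[0])), float(t[-1]))
    mask = t <= t_end + 1e-12
    tt, cc = t[mask], c[mask]
    area = float(np.trapezoid(cc, tt))
    if tt[-1] < t_end - 1e-12:
        c_end = float(np.interp(t_end, t, c))
        area += 0.5 * (cc[-1] + c_end) * (t_end - tt[-1])
    return area


def lambda_z(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> tuple[float | None, dict]:
    """Terminal elimination rate constant by log-linear regression.

    Candidate point sets are the last k samples (k = min_points … all
    available) drawn from the strictly-positive concentrations after Tmax,
    with Tmax itself excluded.  The set maximizing the adjusted R² wins; ties
    within 1e-4 go to the larger set.  Returns (λz, diagnostics); λz is None
    (with a failure flag in the diagnostics) when no candidate has a
    negative slope.
    """
    t, c = profile.times, profile.concentrations
    i_max = int(np.argmax(c))
    mask = (np.arange(t.size) > i_max) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    n = tt.size
    diag: dict = {"n_candidates": 0, "failed": True}
    if n < min_points:
        diag["reason"] = "fewer than min_points positive post-peak samples"
        return None, diag

    # suffix regression statistics via reversed cumulative sums
    rt, ry = tt[::-1], cc[::-1]
    cs_t = np.cumsum(rt)
    cs_y = np.cumsum(ry)
    cs_tt = np.cumsum(rt * rt)
    cs_ty = np.cumsum(rt * ry)
    cs_yy = np.cumsum(ry * ry)
    k = np.arange(1, n + 1, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = cs_tt - cs_t**2 / k
        syy = cs_yy - cs_y**2 / k
        sxy = cs_ty - cs_t * cs_y / k
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), 1.0)
        adj_r2 = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)

    valid = (k >= min_points) & (slope < 0) & np.isfinite(adj_r2)
    diag["n_candidates"] = int(valid.sum())
    if not valid.any():
        diag["reason"] = "no negative-slope candidate"
        return None, diag

    best = np.where(valid, adj_r2, -np.inf).max()
    winners = np.flatnonzero(valid & (adj_r2 >= best - 1e-4))
    i_win = int(winners[-1])  # largest point count among near-ties
    lam = float(-slope[i_win])
    intercept = float((cs_y[i_win] - slope[i_win] * cs_t[i_win]) / k[i_win])
    diag.update(
        failed=False,
        n_points=int(k[i_win]),
        adj_r2=float(adj_r2[i_win]),
        intercept=intercept,
        t_first=float(rt[i_win]),
    )
    return lam, diag


def auc_inf(profile: ConcentrationTimeProfile) -> float:
    """AUC extrapolated to infinity: AUC_last + C_last/λz."""
    lam, diag = lambda_z(profile)
    if lam is None:
        raise ValueError(f"terminal slope estimation failed: {diag.get('reason')}")
    c_last = float(profile.concentrations[-1])
    return auc_trapezoid(profile) + c_last / lam


def nca(
    profile: ConcentrationTimeProfile, window_end: float | None = None
) -> PKParameters:
    """Full non-compartmental summary of a profile.

    ``window_end`` optionally adds an AUC over [t0, window_end], the
    scenario's clinical observation window.
    """
    cmax, tmax = cmax_tmax(profile)
    auc_last = auc_trapezoid(profile)
    lam, diag = lambda_z(profile)
    if lam is not None:
        t_half = math.log(2.0) / lam
        a_inf = auc_last + float(profile.concentrations[-1]) / lam
    else:
        t_half = None
        a_inf = None
    auc_win = (
        auc_trapezoid(profile, window_end) if window_end is not None else None
    )
    return PKParameters(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=a_inf,
        lambda_z=lam,
        t_half=t_half,
        auc_window=auc_win,
        window_end=window_end,
    )


def r_ratio(observed: float, predicted: float) -> float:
    """R ratio = observed / predicted PK parameter."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("observed and predicted must be > 0")
    return observed / predicted


def fold_error(predicted: float, observed: float) -> float:
    """Fold error = predicted / observed PK parameter."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("observed and predicted must be > 0")
    return predicted / observed


def afe(fold_errors: Sequence[float]) -> float:
    """Average fold error: 10^(mean of log10 fold errors) — a geometric mean."""
    fe = np.asarray(list(fold_errors), dtype=float)
    if fe.size == 0:
        raise ValueError("fold error list must be non-empty")
    if np.any(fe <= 0):
        raise ValueError("fold errors must be > 0")
    return float(10.0 ** np.mean(np.log10(fe)))


def rmse_mae(
    simulated: Sequence[float], observed: Sequence[float]
) -> tuple[float, float]:
    """Root-mean-squared and mean-absolute error between paired values."""
    s = np.asarray(list(simulated), dtype=float)
    o = np.asarray(list(observed), dtype=float)
    if s.size != o.size or s.size < 1:
        raise ValueError("simulated and observed must have equal length >= 1")
    diff = s - o
    return float(np.sqrt(np.mean(diff**2))), float(np.mean(np.abs(diff)))


def two_fold_check(r: float) -> bool:
    """True iff the R ratio lies in the acceptable band [0.5, 2.0]."""
    if r <= 0:
        raise ValueError("r must be > 0")
    return 0.5 <= r <= 2.0


def read_profile_csv(path) -> ConcentrationTimeProfile:
    """Read an observed profile CSV with columns time_h, conc_ng_ml."""
    df = pd.read_csv(path)
    missing = {"time_h", "conc_ng_ml"} - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    return ConcentrationTimeProfile(
        df["time_h"].to_numpy(float), df["conc_ng_ml"].to_numpy(float)
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (matching printed-table precision)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")
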