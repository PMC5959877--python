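"""Summary statistics of trial ensembles: bias curves, spreads, diffusion.

All statistics act on the per-trial record (target, response, wrapped
bias, previous target, timing) and are invariant under a global
rotation of targets and responses.  Positional variance over a delay
uses the unwrapped bump displacement so that long delays are not
saturated by wrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._angles import wrap_bias
from .neural_field import results_to_frame

__all__ = [
    "BiasCurve",
    "VarianceCourse",
    "bias_by_relative_angle",
    "peak_bias_vs",
    "response_sd",
    "variance_course",
]


@dataclass
class BiasCurve:
    """Mean/sd of bias binned by the relative angle theta_n - theta_{n+1}."""

    centers: np.ndarray
    mean_bias: np.ndarray
    sd_bias: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rel_angle_deg": self.centers,
                "mean_bias_deg": self.mean_bias,
                "sd_bias_deg": self.sd_bias,
                "count": self.counts,
            }
        )


@dataclass
class VarianceCourse:
    """Across-ensemble variance of unwrapped displacement versus time."""

    times: np.ndarray
    variance: np.ndarray
    ensemble_size: int
    early_slope: float = np.nan  # deg^2/ms over the first 0.5 s
    late_slope: float = np.nan   # deg^2/ms over the final half
    slope_ratio: float = np.nan  # late / early

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "variance_deg2": self.variance})


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return results_to_frame(results)


def _valid(df: pd.DataFrame) -> pd.DataFrame:
    df = df[df["valid"].astype(bool)]
    return df[np.isfinite(df["bias_deg"])]


def bias_by_relative_angle(results, bin_width: float = 18.0) -> BiasCurve:
    """Mean and sd of bias conditioned on theta_n - theta_{n+1}.

    Bins of ``bin_width`` degrees cover (-180, 180]; trials with no
    previous target are excluded, empty bins are reported with count 0.
    """
    df = _valid(_as_frame(results))
    df = df[np.isfinite(df["prev_theta_deg"])]
    rel = wrap_bias(df["prev_theta_deg"].to_numpy() - df["theta_deg"].to_numpy())
    bias = df["bias_deg"].to_numpy()
    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
    centers = edges[:-1] + bin_width / 2.0
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = bias[idx == b]
        counts[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=1) if sel.size > 1 else 0.0
    return BiasCurve(centers, mean, sd, counts)


def peak_bias_vs(results, key: str, bin_width: float = 18.0) -> pd.DataFrame:
    """Peak |mean bias| over relative angle, stratified by T_I or T_D.

    ``key`` is "T_I" or "T_D".  Strata with fewer than one valid trial
    per occupied bin cannot be summarized reliably and are flagged.
    """
    col = {"T_I": "T_I_ms", "T_D": "T_D_ms"}.get(key, key)
    df = _valid(_as_frame(results))
    df = df[np.isfinite(df["prev_theta_deg"])]
    out = []
    for val, grp in df.groupby(col):
        curve = bias_by_relative_angle(grp, bin_width)
        occupied = curve.counts > 0
        peak = float(np.nanmax(np.abs(curve.mean_bias[occupied]))) if occupied.any() else np.nan
        out.append(
            {
                col: val,
                "peak_bias_deg": peak,
                "n_trials": int(len(grp)),
                "flagged": bool(len(grp) < 2 * occupied.sum()),
            }
        )
    return pd.DataFrame(out).sort_values(col, ignore_index=True)


def response_sd(results) -> dict:
    """Spread of the wrapped response error.

    Returns the linear sample sd of the wrapped bias (the convention
    the sigma values quoted for response histograms follow; biases are
    small so it agrees with the circular sd to well under a percent)
    together with the circular sd, both in degrees.
    """
    df = _valid(_as_frame(results))
    bias = df["bias_deg"].to_numpy()
    if bias.size < 2:
        raise ValueError("need at least 2 valid trials")
    return {
        "sd_deg": float(bias.std(ddof=1)),
        "circ_sd_deg": float(np.rad2deg(stats.circstd(np.deg2rad(bias)))),
        "mean_bias_deg": float(bias.mean()),
        "n": int(bias.size),
    }


def variance_course(
    times: np.ndarray, displacement: np.ndarray, early_window_ms: float = 500.0
) -> VarianceCourse:
    """Ensemble variance versus time with a two-phase slope summary.

    ``displacement`` has shape (n_times, n_paths): unwrapped bump
    displacement aligned to delay onset.  The early slope is a linear
    fit over the first ``early_window_ms``; the late slope over the
    final half of the record; their ratio is the two-phase diagnostic
    (near 1 for pure diffusion, well below 1 when facilitation pins
    the bump).
    """
    times = np.asarray(times, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    n_paths = displacement.shape[1]
    if n_paths < 50:
        warnings.warn(f"ensemble of {n_paths} paths is small; variance noisy", stacklevel=2)
    var = displacement.var(axis=1, ddof=1)
    early = times <= early_window_ms
    late = times >= times[-1] / 2.0
    def _slope(mask):
        if mask.sum() < 2:
            return np.nan
        return float(np.polyfit(times[mask], var[mask], 1)[0])
    e, l = _slope(early), _slope(late)
    return VarianceCourse(
        times, var, n_paths, early_slope=e, late_slope=l,
        slope_ratio=l / e if e else np.nan,
    )
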