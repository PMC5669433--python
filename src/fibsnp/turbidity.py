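"""Clot phenotypes from turbidimetric absorbance time series.

A tissue-factor-induced, tPA-lysed plasma clot read at A405 produces a
rise-then-fall turbidity curve. Four phenotypes are derived from it:

* **lag time** (min) — first sustained crossing of a small fraction of
  the amplitude above baseline; activation of coagulation and growth of
  protofibrils to the lateral-aggregation threshold.
* **slope** (au/s, conventionally reported x10^-3) — maximum rate of
  turbidity increase on the rising limb; lateral aggregation rate.
* **maximum absorbance** (au) — plateau minus baseline; proxy for mean
  fibre diameter.
* **CLT, clot lysis time** (min) — time between the half-rise
  (formation midpoint) and the half-fall (lysis midpoint) of the curve.

Levels are detected on a lightly smoothed signal with linear
interpolation between samples; all features are deterministic for a
fixed input and options.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NoClotError(ValueError):
    """Amplitude below the no-clot threshold: no clot formed."""


class InvalidKineticsError(ValueError):
    """Lysis midpoint not after formation midpoint."""


@dataclass
class TurbidityCurve:
    """Absorbance time series. ``time`` in seconds, strictly increasing."""

    time: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape or self.time.ndim != 1:
            raise ValueError("time and absorbance must be equal-length 1-D arrays")
        if self.time.size < 20:
            raise ValueError("need at least 20 samples")
        if np.isnan(self.time).any() or np.isnan(self.absorbance).any():
            raise ValueError("curve contains NaN")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")


@dataclass
class CurveFeatures:
    """Derived clot phenotypes; times in minutes, absorbance in au."""

    lag_min: float
    slope_au_s: float
    max_absorbance: float
    clt_min: float
    baseline: float
    plateau: float
    t_form_mid_min: float
    t_lys_mid_min: float
    qc_flags: frozenset = field(default_factory=frozenset)

    @property
    def slope_e3_au_s(self) -> float:
        return self.slope_au_s * 1e3


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage, odd window."""
    if window <= 1:
        return y.astype(float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    c = np.convolve(y, np.ones(window), mode="same")
    norm = np.convolve(np.ones_like(y), np.ones(window), mode="same")
    return c / norm


def _cross_time(t: np.ndarray, y: np.ndarray, level: float, idx: int, up: bool) -> float:
    """Linear-interpolated crossing time of `level` between idx-1 and idx."""
    if idx == 0:
        return float(t[0])
    y0, y1 = y[idx - 1], y[idx]
    if y1 == y0:
        return float(t[idx])
    frac = (level - y0) / (y1 - y0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def estimate_baseline_plateau(
    curve: TurbidityCurve,
    smooth_window: int = 5,
    no_clot_threshold: float = 0.02,
    lag_frac: float = 0.05,
) -> tuple[float, float]:
    """Robust clear-turbidity baseline and maximum-turbidity plateau.

    The baseline is the median of the 5 smallest values of the smoothed
    record. For a complete rise-and-fall record this is the clear level
    the curve starts from and returns to after lysis; for a record that
    never lyses it reduces to the pre-rise level. The plateau is the
    maximum of the smoothed curve. Raises :class:`NoClotError` when
    plateau - baseline falls below ``no_clot_threshold``.
    """
    y = _smooth(curve.absorbance, smooth_window)
    baseline = float(np.median(np.sort(y)[:5]))
    plateau = float(y.max())
    if plateau - baseline < no_clot_threshold:
        raise NoClotError(
            f"amplitude {plateau - baseline:.4f} au below no-clot threshold"
        )
    return baseline, max(plateau, baseline)


def extract_features(
    curve: TurbidityCurve,
    smooth_window: int = 5,
    lag_frac: float = 0.05,
    sustain: int = 3,
    no_clot_threshold: float = 0.02,
) -> CurveFeatures:
    """Extract the four clot phenotypes from one curve.

    * formation midpoint: first upward crossing of
      baseline + amplitude/2 (linear interpolation between samples)
    * lysis midpoint: last downward crossing of the same level
    * CLT = lysis midpoint - formation midpoint, in minutes
    * slope: maximum first-difference rate on the smoothed rising limb
    * lag: first crossing of baseline + ``lag_frac``*amplitude that
      stays above that level for ``sustain`` consecutive samples

    QC flags: ``CensoredLysis`` when the record ends before the curve
    falls back through the midpoint (CLT undefined, returned as NaN);
    ``MultiPhase`` when the midpoint is crossed upward more than once.
    """
    t = curve.time
    y = _smooth(curve.absorbance, smooth_window)
    baseline, plateau = estimate_baseline_plateau(
        curve, smooth_window, no_clot_threshold, lag_frac
    )
    amplitude = plateau - baseline
    flags = set()

    mid = baseline + amplitude / 2.0
    above_mid = y > mid
    up_idx = np.nonzero(above_mid[1:] & ~above_mid[:-1])[0] + 1
    if up_idx.size == 0:
        raise NoClotError("curve never reaches the formation midpoint")
    if up_idx.size > 1:
        flags.add("MultiPhase")
    i_up = up_idx[0]
    t_form = _cross_time(t, y, mid, i_up, up=True)

    down_idx = np.nonzero(~above_mid[1:] & above_mid[:-1])[0] + 1
    down_idx = down_idx[down_idx > i_up]
    if down_idx.size == 0:
        flags.add("CensoredLysis")
        t_lys = np.nan
    else:
        t_lys = _cross_time(t, y, mid, down_idx[-1], up=False)

    # lag: first sustained crossing of the low level
    lag_level = baseline + lag_frac * amplitude
    above_lag = y > lag_level
    t_lag = np.nan
    run = 0
    for k in range(y.size):
        run = run + 1 if above_lag[k] else 0
        if run >= min(sustain, y.size):
            start = k - run + 1
            t_lag = _cross_time(t, y, lag_level, max(start, 1), up=True)
            break
    if np.isnan(t_lag):
        t_lag = t_form

    # slope on the rising limb of the smoothed curve
    i_peak = int(np.argmax(y))
    if i_peak >= 1:
        rates = np.diff(y[: i_peak + 1]) / np.diff(t[: i_peak + 1])
        slope = float(max(rates.max(), 0.0))
    else:
        slope = 0.0

    clt = (t_lys - t_form) / 60.0 if np.isfinite(t_lys) else np.nan
    return CurveFeatures(
        lag_min=t_lag / 60.0,
        slope_au_s=slope,
        max_absorbance=amplitude,
        clt_min=clt,
        baseline=baseline,
        plateau=plateau,
        t_form_mid_min=t_form / 60.0,
        t_lys_mid_min=t_lys / 60.0 if np.isfinite(t_lys) else np.nan,
        qc_flags=frozenset(flags),
    )


class TurbidityFeatureExtractor:
    """Batch feature extraction with a scikit-learn transformer surface.

    ``transform`` accepts a sequence of :class:`TurbidityCurve` or a
    long-format DataFrame (sample_id, time_s, absorbance_au) and returns
    a per-sample feature frame with units encoded in the column names
    (lag_min, slope_e3_au_s, maxabs_au, clt_min) plus a ``qc_flags``
    column. Curves failing QC yield NaN features and a flag instead of
    raising.
    """

    def __init__(
        self,
        smooth_window: int = 5,
        lag_frac: float = 0.05,
        sustain: int = 3,
        no_clot_threshold: float = 0.02,
    ):
        self.smooth_window = smooth_window
        self.lag_frac = lag_frac
        self.sustain = sustain
        self.no_clot_threshold = no_clot_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            "smooth_window": self.smooth_window,
            "lag_frac": self.lag_frac,
            "sustain": self.sustain,
            "no_clot_threshold": self.no_clot_threshold,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):  # stateless; present for pipeline compatibility
        return self

    def transform(self, X) -> pd.DataFrame:
        curves = as_curves(X)
        rows = []
        for c in curves:
            try:
                f = extract_features(
                    c,
                    smooth_window=self.smooth_window,
                    lag_frac=self.lag_frac,
                    sustain=self.sustain,
                    no_clot_threshold=self.no_clot_threshold,
                )
                rows.append(
                    {
                        "sample_id": c.sample_id,
                        "lag_min": f.lag_min,
                        "slope_e3_au_s": f.slope_e3_au_s,
                        "maxabs_au": f.max_absorbance,
                        "clt_min": f.clt_min,
                        "baseline_au": f.baseline,
                        "plateau_au": f.plateau,
                        "qc_flags": ";".join(sorted(f.qc_flags)),
                    }
                )
            except NoClotError:
                rows.append(
                    {
                        "sample_id": c.sample_id,
                        "lag_min": np.nan,
                        "slope_e3_au_s": np.nan,
                        "maxabs_au": np.nan,
                        "clt_min": np.nan,
                        "baseline_au": np.nan,
                        "plateau_au": np.nan,
                        "qc_flags": "NoClot",
                    }
                )
        return pd.DataFrame(rows)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def as_curves(X) -> list[TurbidityCurve]:
    """Coerce a long-format DataFrame or a curve sequence to curves."""
    if isinstance(X, pd.DataFrame):
        out = []
        for sid, grp in X.groupby("sample_id", sort=True):
            grp = grp.sort_values("time_s")
            out.append(
                TurbidityCurve(
                    grp["time_s"].to_numpy(),
                    grp["absorbance_au"].to_numpy(),
                    sample_id=str(sid),
                )
            )
        return out
    return list(X)


def read_curves_long(path) -> list[TurbidityCurve]:
    """Long-format CSV: sample_id, time_s, absorbance_au."""
    return as_curves(pd.read_csv(path))


def write_curves_long(curves, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": c.sample_id,
                "time_s": c.time,
                "absorbance_au": c.absorbance,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)
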