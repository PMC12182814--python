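"""Per-slice mechanical dyssynchrony statistics from segmental strain curves.

Four statistics are computed per short-axis slice, on the radial channel:

sdTTP   population standard deviation of segmental time to peak (ms),
maxTTP  maximum segmental time to peak (ms),
SRCC    strain-rate cross correlation: the mean (or max) absolute lag, over
        all unordered segment pairs, that maximizes the circular normalized
        cross-correlation of the two strain-rate curves, in ms,
RURE    radial uniformity ratio estimate: with A0(t), A1(t) the magnitudes of
        the order-0 and order-1 spatial Fourier coefficients of segmental
        strain around the circumference, RURE = sum_t A0 / sum_t (A0 + A1).
        1 means perfectly uniform contraction; 0 a pure opposing-wall
        (first-harmonic) pattern.

All are deterministic functions of the curves and invariant to positive
rescaling of the strain curves (lags, argmax times, and Fourier-magnitude
ratios are scale-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strain import SegmentCurves

__all__ = ["DyssynchronyMetrics", "time_to_peak", "sd_ttp", "max_ttp",
           "srcc", "rure", "slice_metrics"]


@dataclass
class DyssynchronyMetrics:
    sdTTP_ms: float
    maxTTP_ms: float
    SRCC_ms: float
    RURE: float
    slice_level: str

    def to_dict(self) -> dict:
        return {"slice": self.slice_level, "sdTTP_ms": self.sdTTP_ms,
                "maxTTP_ms": self.maxTTP_ms, "SRCC_ms": self.SRCC_ms,
                "RURE": self.RURE}


def time_to_peak(curves: SegmentCurves, flat_tol: float = 1e-12) -> np.ndarray:
    """Segmental time to peak strain, ms; NaN for flat (non-contracting) curves."""
    out = np.full(len(curves.names), np.nan)
    for s in range(len(curves.names)):
        c = curves.strain[s]
        if np.ptp(c) > flat_tol:
            out[s] = int(np.argmax(c)) * curves.frame_duration_ms
    return out


def sd_ttp(ttp_ms: np.ndarray) -> float:
    """Population standard deviation (divisor n) of the defined segmental TTPs."""
    vals = np.asarray(ttp_ms, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError(f"sd_ttp needs >= 2 defined TTPs, got {len(vals)}")
    return float(np.std(vals))


def max_ttp(ttp_ms: np.ndarray) -> float:
    vals = np.asarray(ttp_ms, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("max_ttp needs at least one defined TTP")
    return float(vals.max())


def _best_circular_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> int:
    """Lag in [-max_lag, max_lag] maximizing the circular cross-correlation of
    zero-mean curves; ties broken to the smallest |lag|, then the negative lag."""
    a = a - a.mean()
    b = b - b.mean()
    best_lag, best_val = None, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda g: (abs(g), g)):
        val = float(a @ np.roll(b, -lag))
        if best_lag is None or val > best_val + 1e-12 * max(1.0, abs(best_val)):
            best_val, best_lag = val, lag
    return best_lag


def srcc(curves: SegmentCurves, aggregation: str = "mean") -> float:
    """Strain-rate cross-correlation lag statistic, ms.

    For every unordered segment pair, the strain-rate curves are zero-mean
    normalized and the circular cross-correlation is searched over lags up to
    half the cycle; the statistic is the mean (default) or max of the absolute
    pairwise lags, converted to ms.  Pairs containing a zero-variance curve
    are skipped; if all pairs are skipped an error is raised.
    """
    if aggregation not in ("mean", "max"):
        raise ValueError(f"unknown SRCC aggregation {aggregation!r}")
    n_seg, n_frames = curves.strain_rate.shape
    if n_seg < 2:
        raise ValueError("SRCC needs >= 2 segments")
    max_lag = n_frames // 2
    lags = []
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            a, b = curves.strain_rate[i], curves.strain_rate[j]
            if np.std(a) == 0.0 or np.std(b) == 0.0:
                continue
            lags.append(abs(_best_circular_lag(a, b, max_lag)))
    if not lags:
        raise ValueError("SRCC undefined: all segment pairs had a zero-variance curve")
    agg = np.mean if aggregation == "mean" else np.max
    return float(agg(lags)) * curves.frame_duration_ms


def rure(curves: SegmentCurves, variant: str = "summed") -> float:
    """Radial uniformity ratio estimate in [0, 1].

    Segments are taken in circumferential order (the curve ordering).  Per
    frame, A0 and A1 are the magnitudes of the order-0 and order-1 discrete
    Fourier coefficients of the segmental strain values.  ``summed`` (default)
    returns sum_t A0 / sum_t (A0 + A1); ``framewise`` averages A0/(A0+A1) over
    frames.  Frames with A0 + A1 = 0 are excluded; if all frames are excluded
    the estimate is undefined (NaN).
    """
    if variant not in ("summed", "framewise"):
        raise ValueError(f"unknown RURE variant {variant!r}")
    n_seg = curves.strain.shape[0]
    if n_seg < 4:
        raise ValueError("RURE needs >= 4 segments")
    coeffs = np.fft.fft(curves.strain, axis=0)   # over segments, per frame
    a0 = np.abs(coeffs[0])
    a1 = np.abs(coeffs[1])
    denom = a0 + a1
    ok = denom > 1e-300
    if not ok.any():
        return float("nan")
    if variant == "summed":
        return float(a0[ok].sum() / denom[ok].sum())
    return float(np.mean(a0[ok] / denom[ok]))


def slice_metrics(curves: SegmentCurves, srcc_aggregation: str = "mean",
                  rure_variant: str = "summed") -> DyssynchronyMetrics:
    """Bundle the four dyssynchrony statistics for one slice (radial channel).

    Fully non-contracting slices (all curves flat) produce a missing-value
    record rather than an error.
    """
    ttp = time_to_peak(curves)
    if np.isfinite(ttp).sum() < 2:
        return DyssynchronyMetrics(sdTTP_ms=float("nan"), maxTTP_ms=float("nan"),
                                   SRCC_ms=float("nan"), RURE=float("nan"),
                                   slice_level=curves.slice_level)
    return DyssynchronyMetrics(
        sdTTP_ms=sd_ttp(ttp),
        maxTTP_ms=max_ttp(ttp),
        SRCC_ms=srcc(curves, aggregation=srcc_aggregation),
        RURE=rure(curves, variant=rure_variant),
        slice_level=curves.slice_level,
    )


def metrics_frame(metrics: list[DyssynchronyMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in metrics])
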