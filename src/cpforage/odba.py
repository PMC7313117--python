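"""Overall dynamic body acceleration (ODBA) from tri-axial accelerometry.

The static (postural/gravitational) component of each axis is estimated by a
centred 1-s running mean; the residual is the dynamic component, and ODBA is
the sum of the absolute dynamic components across the three axes.  The
trip-level statistic is the mean per-sample ODBA over the trip window, a
proxy for mass-specific energy expenditure in birds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def running_mean_centered(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with shrinking windows at the edges."""
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError("window longer than the signal")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def static_dynamic_split(
    acc: pd.DataFrame, window_samples: int = 25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split raw acceleration into static and dynamic components per axis.

    ``acc`` must hold columns ``ax``, ``ay``, ``az`` (units g); 25 samples is
    1 s at the 25 Hz logging rate.  ``static + dynamic == raw`` exactly.
    """
    axes = ["ax", "ay", "az"]
    static = pd.DataFrame(
        {a: running_mean_centered(acc[a].to_numpy(dtype=float), window_samples) for a in axes},
        index=acc.index,
    )
    dynamic = acc[axes].astype(float) - static
    return static, dynamic


def odba_series(dynamic: pd.DataFrame) -> np.ndarray:
    """Per-sample ODBA: |dx| + |dy| + |dz| (units g)."""
    return (
        np.abs(dynamic["ax"].to_numpy(dtype=float))
        + np.abs(dynamic["ay"].to_numpy(dtype=float))
        + np.abs(dynamic["az"].to_numpy(dtype=float))
    )


def trip_odba(t: np.ndarray, odba_t: np.ndarray, start_t, end_t) -> float:
    """Mean per-sample ODBA over samples inside [start_t, end_t]; NaN if none."""
    t = pd.to_datetime(pd.Series(np.asarray(t))).to_numpy()
    mask = (t >= np.datetime64(pd.Timestamp(start_t))) & (
        t <= np.datetime64(pd.Timestamp(end_t))
    )
    if not mask.any():
        return float("nan")
    return float(np.mean(np.asarray(odba_t, dtype=float)[mask]))


def odba_for_stream(acc: pd.DataFrame, window_samples: int = 25) -> np.ndarray:
    """Convenience: per-sample ODBA straight from a raw tri-axial stream."""
    _, dyn = static_dynamic_split(acc, window_samples)
    return odba_series(dyn)
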