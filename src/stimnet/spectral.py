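"""Welch spectral densities and band power across stimulation levels.

Band power is the trapezoidal integral of the one-sided Welch density
(1-s Hamming windows, 50% overlap) over the band, inclusive of both edges;
absolute, not relative, power. Per-condition level slopes reuse the ordinal
OLS slope of the kinematics module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import DEFAULT_BANDS, BandDefinition, MultichannelRecording
from .kinematics import slope_across_levels

__all__ = ["PSD", "welch_psd", "band_power", "power_table", "power_slopes"]


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density on a frequency grid."""

    freqs: np.ndarray
    density: np.ndarray  # (..., n_freqs), signal^2 per Hz

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")


def welch_psd(series: np.ndarray, fs: float, win_s: float = 1.0,
              overlap: float = 0.5, window: str = "hamming") -> PSD:
    """Welch periodogram with ``win_s``-second windows; resolution 1/win_s Hz."""
    x = np.asarray(series, dtype=float)
    nperseg = int(round(win_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"series of {x.shape[-1]} samples is shorter than one "
            f"{win_s:g}-s window ({nperseg} samples)")
    freqs, dens = signal.welch(x, fs=fs, window=window, nperseg=nperseg,
                               noverlap=int(round(nperseg * overlap)),
                               detrend="constant", scaling="density", axis=-1)
    return PSD(freqs=freqs, density=dens)


def band_power(psd: PSD, band: BandDefinition) -> float | np.ndarray:
    """Trapezoidal integral of the density over [band.lo, band.hi]."""
    if band.hi > psd.freqs[-1]:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds the PSD "
            f"range (max {psd.freqs[-1]:g} Hz)")
    mask = band.contains(psd.freqs)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 grid points")
    pw = np.trapezoid(psd.density[..., mask], psd.freqs[mask], axis=-1)
    return float(pw) if np.ndim(pw) == 0 else pw


def power_table(sources_by_level: dict[int, MultichannelRecording],
                bands: dict[str, BandDefinition] | None = None,
                subject: str = "s01", task: str = "self_paced",
                win_s: float = 1.0) -> pd.DataFrame:
    """Long-format band-power table over ROI x band x stimulation level."""
    if bands is None:
        bands = DEFAULT_BANDS
    rows = []
    for level, rec in sorted(sources_by_level.items()):
        psd = welch_psd(rec.data, rec.fs_hz, win_s=win_s)
        for band in bands.values():
            powers = band_power(psd, band)
            for roi, pw in zip(rec.labels, np.atleast_1d(powers)):
                rows.append({"subject": subject, "task": task, "roi": roi,
                             "band": band.name, "level": level,
                             "power": float(pw)})
    return pd.DataFrame(rows)


def power_slopes(table: pd.DataFrame, log_power: bool = False) -> pd.DataFrame:
    """Per-(subject, task, roi, band) OLS slope of power across levels.

    Conditions with fewer than 4 levels are fitted on the available levels
    and flagged in the ``complete`` column.
    """
    rows = []
    for (subject, task, roi, band), grp in table.groupby(
            ["subject", "task", "roi", "band"], sort=True):
        vals = {int(lv): (np.log(p) if log_power else p)
                for lv, p in zip(grp["level"], grp["power"])}
        res = slope_across_levels(vals)
        rows.append({"subject": subject, "task": task, "roi": roi,
                     "band": band, "slope": res.slope,
                     "intercept": res.intercept,
                     "complete": len(res.levels) == 4})
    return pd.DataFrame(rows)
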