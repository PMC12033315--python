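"""LCMV beamforming: spatial filters from a lead field and data covariance.

The linearly constrained minimum-variance filter for a source with lead
column l is w = (l' C^-1 l)^-1 l' C^-1: it passes that source with unit gain
(w' l = 1) while minimizing the output variance w' C w, thereby suppressing
every other source. Sources are scalar (one fixed-orientation lead column
per region of interest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import LeadField, MultichannelRecording

__all__ = [
    "SpatialFilterSet",
    "estimate_covariance",
    "lcmv_filters",
    "extract_sources",
    "LCMVBeamformer",
]

#: Condition-number ceiling beyond which the covariance inverse is refused.
_COND_LIMIT = 1e12


@dataclass
class SpatialFilterSet:
    """Beamformer weights (sources x sensors) plus fit diagnostics."""

    weights: np.ndarray
    source_labels: tuple[str, ...]
    sensor_labels: tuple[str, ...]
    shrinkage: float
    cov_condition: float


def estimate_covariance(rec: MultichannelRecording,
                        shrinkage: float = 0.0) -> np.ndarray:
    """Sensor covariance with optional diagonal loading.

    Loading adds ``shrinkage * mean(diag(C))`` to the diagonal, the common
    remedy for rank-deficient or short recordings. Constant channels are
    rejected by name. When there are fewer samples than sensors the sample
    covariance is singular, so loading is mandatory.
    """
    x = rec.data
    sds = x.std(axis=1)
    dead = [lab for lab, sd in zip(rec.labels, sds) if sd == 0]
    if dead:
        raise ValueError(f"constant channels cannot enter the covariance: {dead}")
    if rec.n_samples < rec.n_channels and shrinkage <= 0:
        raise ValueError("fewer samples than sensors: shrinkage is mandatory")
    c = np.cov(x)
    c = np.atleast_2d(c)
    if shrinkage > 0:
        c = c + shrinkage * np.mean(np.diag(c)) * np.eye(c.shape[0])
    return c


def lcmv_filters(leadfield: LeadField, cov: np.ndarray,
                 shrinkage: float = 0.0) -> SpatialFilterSet:
    """LCMV weights for every lead column; unit gain holds by construction."""
    c = np.asarray(cov, dtype=float)
    if shrinkage > 0:
        c = c + shrinkage * np.mean(np.diag(c)) * np.eye(c.shape[0])
    cond = float(np.linalg.cond(c))
    if cond > _COND_LIMIT:
        raise ValueError(
            f"covariance condition number {cond:.2e} too large; "
            "increase the shrinkage (diagonal loading)")
    l_mat = leadfield.matrix  # sensors x sources
    ci_l = linalg.solve(c, l_mat, assume_a="pos")  # C^-1 L
    gains = np.einsum("ij,ij->j", l_mat, ci_l)  # l_s' C^-1 l_s per source
    if np.any(gains <= 0):
        raise ValueError("non-positive beamformer normalization; covariance "
                         "is not positive definite")
    weights = (ci_l / gains).T  # sources x sensors
    return SpatialFilterSet(
        weights=weights,
        source_labels=leadfield.source_labels,
        sensor_labels=leadfield.sensor_labels,
        shrinkage=shrinkage,
        cov_condition=cond,
    )


def extract_sources(rec: MultichannelRecording,
                    filters: SpatialFilterSet) -> MultichannelRecording:
    """Apply beamformer weights: source data = W @ sensor data."""
    if rec.labels != filters.sensor_labels:
        raise ValueError("recording channel labels do not match the filters")
    return MultichannelRecording(
        data=filters.weights @ rec.data,
        fs_hz=rec.fs_hz,
        labels=filters.source_labels,
        space="source",
    )


class LCMVBeamformer(BaseEstimator, TransformerMixin):
    """sklearn-style LCMV transformer over (n_samples, n_sensors) arrays.

    Parameters
    ----------
    leadfield : LeadField
        Forward matrix (sensors x sources) with labels.
    shrinkage : float, default 0.05
        Diagonal loading as a fraction of the mean sensor variance.

    Attributes
    ----------
    filters_ : SpatialFilterSet
    covariance_ : ndarray, the loaded sensor covariance used for the fit.
    """

    def __init__(self, leadfield: LeadField, shrinkage: float = 0.05):
        self.leadfield = leadfield
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y=None) -> "LCMVBeamformer":
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.leadfield.n_sensors:
            raise ValueError("X must be (n_samples, n_sensors)")
        rec = MultichannelRecording(data=x.T, fs_hz=1.0,
                                    labels=self.leadfield.sensor_labels)
        cov = estimate_covariance(rec, shrinkage=self.shrinkage)
        self.covariance_ = cov
        self.filters_ = lcmv_filters(self.leadfield, cov)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "filters_"):
            raise RuntimeError("LCMVBeamformer is not fitted")
        return np.asarray(X, dtype=float) @ self.filters_.weights.T
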