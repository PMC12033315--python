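"""Core data containers shared across the pipeline stages.

Units are pinned package-wide: centimetres and seconds for pen traces, Hz for
all frequencies, one-sided spectral densities, and ordered (source, target)
pairs for directed edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eight regions of interest whose source series the analysis uses:
#: primary motor cortex, supplementary and pre-supplementary motor areas,
#: dorsal/ventral premotor cortices, dorsolateral prefrontal cortex, visual
#: cortex, and the subthalamic nucleus.
ROI_LABELS = ("M1", "SMA", "preSMA", "DPMC", "VPMC", "DLPFC", "VC", "STN")

#: Subset entering the directed-connectivity (gPDC) analysis.
CONNECTIVITY_ROIS = ("M1", "SMA", "DPMC", "VPMC", "STN")

#: Stimulation levels are ordinal 0 (off) .. 3 (maximal tolerated).
LEVELS = (0, 1, 2, 3)

TASKS = ("self_paced", "traced")


@dataclass(frozen=True)
class BandDefinition:
    """A named analysis band, inclusive of both edges, in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo={self.lo} must be < hi={self.hi}")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs <= self.hi)


#: The four analysis bands.
DEFAULT_BANDS = {
    "low_beta": BandDefinition("low_beta", 13.0, 20.0),
    "high_beta": BandDefinition("high_beta", 21.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 31.0, 60.0),
    "high_gamma": BandDefinition("high_gamma", 61.0, 100.0),
}


@dataclass
class SpiralTrace:
    """One drawn spiral: time-stamped pen positions plus condition metadata.

    Attributes
    ----------
    t : array of seconds, strictly increasing.
    x, y : pen position in cm.
    task : "self_paced" or "traced".
    level : stimulation level 0..3.
    repeat : repetition index 1..5 within a condition.
    subject : subject identifier.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    task: str = "self_paced"
    level: int = 0
    repeat: int = 1
    subject: str = "s01"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size < 3:
            raise ValueError("a spiral trace needs at least 3 samples")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.level not in LEVELS:
            raise ValueError(f"stimulation level must be 0..3, got {self.level}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def fs_hz(self) -> float:
        """Nominal sampling rate from the median sample interval."""
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class MultichannelRecording:
    """Channels x samples matrix with a sampling rate, in sensor or source space."""

    data: np.ndarray
    fs_hz: float
    labels: tuple[str, ...]
    space: str = "sensor"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(self.labels)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.space not in ("sensor", "source"):
            raise ValueError(f"space must be 'sensor' or 'source', got {self.space!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, data: np.ndarray, space: str | None = None,
                  labels: tuple[str, ...] | None = None) -> "MultichannelRecording":
        return MultichannelRecording(
            data=data,
            fs_hz=self.fs_hz,
            labels=self.labels if labels is None else tuple(labels),
            space=self.space if space is None else space,
        )


@dataclass
class LeadField:
    """Forward mixing matrix mapping source activity to sensor potentials."""

    matrix: np.ndarray  # sensors x sources
    sensor_labels: tuple[str, ...]
    source_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sensor_labels = tuple(self.sensor_labels)
        self.source_labels = tuple(self.source_labels)
        n_sens, n_src = self.matrix.shape
        if len(self.sensor_labels) != n_sens or len(self.source_labels) != n_src:
            raise ValueError("lead-field labels inconsistent with matrix shape")
        if np.linalg.matrix_rank(self.matrix) < n_src:
            raise ValueError("lead field is column-rank deficient")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MVARModel:
    """A multivariate autoregressive process x_t = sum_r A_r x_{t-r} + e_t.

    ``A`` is shaped (p, K, K) with ``A[r-1][i, j]`` the influence of region j
    at lag r on region i; ``Sigma`` is the innovation covariance. The model is
    the generative object behind generalized partial directed coherence.
    """

    A: np.ndarray
    Sigma: np.ndarray
    fs_hz: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must be shaped (p, K, K)")
        k = self.A.shape[1]
        if self.Sigma.shape != (k, k):
            raise ValueError("Sigma shape inconsistent with A")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma) < -1e-10):
            raise ValueError("Sigma must be positive semi-definite")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(k))
        if len(self.labels) != k:
            raise ValueError("label count inconsistent with A")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]

    @property
    def sigma(self) -> np.ndarray:
        """Per-region innovation standard deviations sqrt(diag(Sigma))."""
        return np.sqrt(np.diag(self.Sigma))

    def companion(self) -> np.ndarray:
        """Companion (stacked first-order) coefficient matrix, (pK, pK)."""
        p, k = self.p, self.k
        comp = np.zeros((p * k, p * k))
        comp[:k] = np.concatenate(list(self.A), axis=1)
        if p > 1:
            comp[k:, :-k] = np.eye((p - 1) * k)
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol


@dataclass
class GPDCSpectrum:
    """|pi_ij(f)| directed-coherence tensor on a frequency grid.

    ``pi_abs[i, j, f]`` is the normalized directed influence of region j on
    region i at frequency ``freqs[f]``; columns satisfy
    sum_i |pi_ij(f)|^2 = 1. ``Abar`` retains the frequency-transformed
    coefficient matrices for diagnostics.
    """

    freqs: np.ndarray
    pi_abs: np.ndarray  # K x K x F
    Abar: np.ndarray  # F x K x K, complex
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        col_norm = np.sum(self.pi_abs**2, axis=0)  # K x F
        if not np.allclose(col_norm, 1.0, atol=1e-8):
            raise ValueError("gPDC column normalization violated")
        if np.any(self.pi_abs < -1e-12) or np.any(self.pi_abs > 1 + 1e-12):
            raise ValueError("gPDC values outside [0, 1]")
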