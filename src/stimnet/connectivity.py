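"""Generalized partial directed coherence from multivariate AR models.

Given a fitted MVAR model x_t = sum_r A_r x_{t-r} + e_t with innovation
variances sigma_k^2, the frequency-transformed coefficients are

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)

and the generalized partial directed coherence from region j to region i is

    |pi_ij(f)| = (1/sigma_i) |Abar_ij(f)|
                 / sqrt( sum_k (1/sigma_k^2) |Abar_kj(f)|^2 )

a normalized directed-outflow ratio: the outflow from j to i relative to all
outflows from j. Every column satisfies sum_i |pi_ij(f)|^2 = 1 and values
lie in [0, 1]. Weighting by the innovation standard deviations makes the
measure invariant to the scale of the individual signals.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    DEFAULT_BANDS,
    BandDefinition,
    GPDCSpectrum,
    MultichannelRecording,
    MVARModel,
)

__all__ = [
    "MVAR",
    "fit_mvar",
    "spectral_transfer",
    "gpdc",
    "band_mean_gpdc",
    "default_freq_grid",
    "phase_randomized",
    "gpdc_surrogate_null",
]


def default_freq_grid() -> np.ndarray:
    """0.5 Hz spacing over 1-100 Hz: covers all four analysis bands."""
    return np.arange(1.0, 100.0 + 0.25, 0.5)


# ---------------------------------------------------------------------------
# MVAR estimation
# ---------------------------------------------------------------------------

class MVAR(BaseEstimator):
    """Least-squares multivariate autoregressive estimator.

    Parameters
    ----------
    order : int or "bic"
        Fixed model order, or BIC selection over 1..``max_order``.
    max_order : int, default 20
        Upper bound for BIC selection.

    Attributes
    ----------
    coef_ : ndarray (p, K, K), lag coefficient matrices.
    sigma_ : ndarray (K, K), residual innovation covariance (df-corrected).
    order_ : int, selected order.
    bic_ : ndarray of BIC values when order selection ran.
    """

    def __init__(self, order: int | str = "bic", max_order: int = 20):
        self.order = order
        self.max_order = max_order

    def fit(self, X: np.ndarray, y=None) -> "MVAR":
        x = np.asarray(X, dtype=float)
        if x.ndim != 2:
            raise ValueError("X must be (n_samples, K)")
        n, k = x.shape
        if self.order == "bic":
            bics = np.array([self._fit_order(x, p, compute_only_bic=True)
                             for p in range(1, self.max_order + 1)])
            self.bic_ = bics
            p = int(np.argmin(bics)) + 1
        else:
            p = int(self.order)
            if p < 1:
                raise ValueError("order must be >= 1")
        if n <= 10 * p * k:
            warnings.warn(f"only {n} samples for K={k}, p={p}; estimates "
                          "may be unreliable", stacklevel=2)
        self.coef_, self.sigma_ = self._fit_order(x, p)
        self.order_ = p
        self.n_samples_ = n
        return self

    @staticmethod
    def _fit_order(x: np.ndarray, p: int, compute_only_bic: bool = False):
        n, k = x.shape
        if n - p <= k * p:
            raise ValueError(f"too few samples ({n}) to fit order {p}")
        # Design: rows are [x_{t-1}, ..., x_{t-p}] flattened, newest first.
        y = x[p:]
        z = np.concatenate([x[p - r:n - r] for r in range(1, p + 1)], axis=1)
        coef_flat, _, rank, _ = np.linalg.lstsq(z, y, rcond=None)
        if rank < k * p:
            raise ValueError("singular regressor matrix in MVAR fit")
        resid = y - z @ coef_flat
        n_eff = n - p
        dof = n_eff - k * p
        sigma = resid.T @ resid / max(dof, 1)
        if compute_only_bic:
            sign, logdet = np.linalg.slogdet(resid.T @ resid / n_eff)
            if sign <= 0:
                return np.inf
            return logdet + np.log(n_eff) * p * k * k / n_eff
        coef = coef_flat.T.reshape(k, p, k).transpose(1, 0, 2)
        return coef, sigma

    def to_model(self, fs_hz: float,
                 labels: tuple[str, ...] | None = None) -> MVARModel:
        if not hasattr(self, "coef_"):
            raise RuntimeError("MVAR is not fitted")
        model = MVARModel(A=self.coef_, Sigma=self.sigma_, fs_hz=fs_hz,
                          labels=labels or ())
        if not model.is_stable():
            warnings.warn("fitted MVAR model is unstable (spectral radius "
                          f"{model.spectral_radius():.3f})", stacklevel=2)
        return model


def fit_mvar(sources: MultichannelRecording, order: int | str = "bic",
             max_order: int = 20) -> MVARModel:
    """Fit an MVAR model to a source-space recording (channels x samples)."""
    est = MVAR(order=order, max_order=max_order).fit(sources.data.T)
    return est.to_model(sources.fs_hz, labels=sources.labels)


# ---------------------------------------------------------------------------
# gPDC
# ---------------------------------------------------------------------------

def spectral_transfer(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs); shape (F, K, K)."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > model.fs_hz / 2):
        raise ValueError("frequencies must lie in [0, fs/2]")
    r = np.arange(1, model.p + 1)
    # phase[f, r] = exp(-i 2 pi f r / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, r) / model.fs_hz)
    abar = np.eye(model.k)[None] - np.einsum("fr,rij->fij", phase, model.A)
    return abar


def gpdc(model: MVARModel, freqs: np.ndarray | None = None) -> GPDCSpectrum:
    """Generalized partial directed coherence |pi_ij(f)| of the model.

    The innovation variances are read from the diagonal of Sigma; zero
    variances are rejected. The column-normalization invariant
    sum_i |pi_ij|^2 = 1 holds by construction and is asserted on the result.
    """
    if freqs is None:
        freqs = default_freq_grid()
    sig2 = np.diag(model.Sigma)
    if np.any(sig2 <= 0):
        raise ValueError("zero innovation variance: gPDC undefined")
    abar = spectral_transfer(model, freqs)  # F x K x K
    w = np.abs(abar) / np.sqrt(sig2)[None, :, None]  # (1/sigma_i)|Abar_ij|
    denom = np.sqrt(np.sum(w**2, axis=1, keepdims=True))  # per column j
    pi_abs = np.transpose(w / denom, (1, 2, 0))  # K x K x F
    return GPDCSpectrum(freqs=np.asarray(freqs, dtype=float), pi_abs=pi_abs,
                        Abar=abar, labels=model.labels)


def band_mean_gpdc(spec: GPDCSpectrum, band: BandDefinition,
                   pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Arithmetic mean of |pi| over the band's grid points, per ordered pair.

    ``pairs`` are (source, target) tuples; by default all ordered non-self
    pairs of the spectrum's labels.
    """
    mask = band.contains(spec.freqs)
    if not mask.any():
        raise ValueError(f"no frequency grid points inside band {band.name}")
    idx = {lab: i for i, lab in enumerate(spec.labels)}
    if pairs is None:
        pairs = [(s, t) for s, t in itertools.permutations(spec.labels, 2)]
    rows = []
    for src, dst in pairs:
        if src == dst:
            raise ValueError("self-pairs are not part of the connectivity table")
        val = float(spec.pi_abs[idx[dst], idx[src], mask].mean())
        rows.append({"band": band.name, "source": src, "target": dst,
                     "gpdc": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surrogate utility
# ---------------------------------------------------------------------------

def phase_randomized(data: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent phase randomization per channel (channels x samples).

    Preserves each channel's amplitude spectrum while destroying all
    cross-channel phase structure; the classic null for directed measures.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n, axis=-1)


def gpdc_surrogate_null(sources: MultichannelRecording, band: BandDefinition,
                        pairs: list[tuple[str, str]], order: int,
                        n_surrogates: int = 100, seed: int | None = None,
                        percentile: float = 95.0) -> dict[tuple[str, str], float]:
    """Percentile of band-mean gPDC under phase-randomized surrogates."""
    rng = np.random.default_rng(seed)
    vals: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
    for _ in range(n_surrogates):
        surr = sources.copy_with(phase_randomized(sources.data, rng))
        model = fit_mvar(surr, order=order)
        table = band_mean_gpdc(gpdc(model), band, pairs)
        for _, row in table.iterrows():
            vals[(row["source"], row["target"])].append(row["gpdc"])
    return {p: float(np.percentile(v, percentile)) for p, v in vals.items()}


def connectivity_table(sources_by_level: dict[int, MultichannelRecording],
                       pairs: list[tuple[str, str]] | None = None,
                       bands: dict[str, BandDefinition] | None = None,
                       order: int | str = "bic", max_order: int = 20,
                       subject: str = "s01",
                       task: str = "self_paced") -> pd.DataFrame:
    """Band-mean gPDC per (source, target, band, level), long format."""
    if bands is None:
        bands = DEFAULT_BANDS
    rows = []
    for level, rec in sorted(sources_by_level.items()):
        model = fit_mvar(rec, order=order, max_order=max_order)
        spec = gpdc(model)
        for band in bands.values():
            tab = band_mean_gpdc(spec, band, pairs)
            tab.insert(0, "subject", subject)
            tab.insert(1, "task", task)
            tab["level"] = level
            rows.append(tab)
    return pd.concat(rows, ignore_index=True)
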