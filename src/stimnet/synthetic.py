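"""Synthetic spiral traces and neural recordings with known ground truth.

The generator emulates the study conditions the downstream analysis assumes:
Archimedean spirals drawn under 4 stimulation levels x 2 tasks x 5 repeats
with a stimulation-dependent velocity increase and entropy decrease, and
multichannel signals from a stable MVAR process whose band-limited directed
couplings are modulated by stimulation level (high-beta subthalamo-cortical
edges weaken with level, high-gamma premotor-to-M1 edges strengthen), mixed
to sensors through a smooth random lead field with additive noise, 50 Hz line
contamination and an optional ~130 Hz stimulation pulse train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import (
    CONNECTIVITY_ROIS,
    LEVELS,
    ROI_LABELS,
    TASKS,
    LeadField,
    MultichannelRecording,
    MVARModel,
    SpiralTrace,
)

__all__ = [
    "SpiralGenConfig",
    "EffectSpec",
    "Oscillator",
    "Edge",
    "NetworkSpec",
    "SensorModelSpec",
    "gen_spiral",
    "gen_cohort_spirals",
    "analytic_mean_speed",
    "build_mvar_from_spec",
    "default_motor_network",
    "simulate_mvar",
    "simulate_mvar_ensemble",
    "project_to_sensors",
    "gen_feature_cohort",
]


# ---------------------------------------------------------------------------
# Spiral drawing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpiralGenConfig:
    """Parameters of the Archimedean-spiral pen model r = b * theta / (2*pi).

    ``spacing_cm`` is the loop spacing b (template spacing 1.5 cm), drawn over
    ``n_loops`` full turns at tablet rate ``fs_hz``. The pen advances at
    angular speed ``base_angular_speed * (1 + level_speed_gain * level)``
    rad/s, optionally modulated by a smooth random process of relative
    amplitude ``entropy_knob`` (higher values make the tangential-velocity
    series more irregular, i.e. raise its sample entropy). ``jitter_sd`` adds
    isotropic positional noise and ``tremor_amp``/``tremor_hz`` an optional
    oscillatory contamination, both in cm.
    """

    spacing_cm: float = 1.5
    n_loops: int = 3
    fs_hz: float = 100.0
    base_angular_speed: float = 1.3  # rad/s; ~14 s for three loops at level 0
    level_speed_gain: float = 0.15
    jitter_sd: float = 0.0
    tremor_amp: float = 0.0
    tremor_hz: float = 5.0
    entropy_knob: float = 0.0
    direction: str = "counterclockwise"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be positive")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")
        if self.level_speed_gain < 0:
            raise ValueError("level_speed_gain must be >= 0")
        if self.base_angular_speed <= 0:
            raise ValueError("base_angular_speed must be positive")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _angular_speed(cfg: SpiralGenConfig, level: int) -> float:
    return cfg.base_angular_speed * (1.0 + cfg.level_speed_gain * level)


def analytic_mean_speed(cfg: SpiralGenConfig, level: int) -> float:
    """Noise-free sample mean of the tangential velocity of a generated spiral.

    With constant angular speed w the tangential speed is
    v(t) = (b / 2 pi) * w^2 * t, so its time average over the full draw of
    duration T = 2 pi n / w is b * n * w / 2.
    """
    w = _angular_speed(cfg, level)
    return cfg.spacing_cm * cfg.n_loops * w / 2.0


def gen_spiral(cfg: SpiralGenConfig, level: int,
               rng: np.random.Generator | None = None, *,
               task: str = "self_paced", repeat: int = 1,
               subject: str = "s01") -> SpiralTrace:
    """Generate one spiral trace drawn at the given stimulation level.

    The trace starts at the center, the radius grows monotonically (up to
    jitter) and the draw ends exactly after ``n_loops`` turns. The last sample
    is placed on the time grid by an O(dt/T) adjustment of the effective
    angular speed, so a noise-free spiral ends at radius
    ``spacing_cm * n_loops`` exactly.
    """
    if level not in LEVELS:
        raise ValueError(f"stimulation level must be 0..3, got {level}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    w = _angular_speed(cfg, level)
    theta_total = 2.0 * np.pi * cfg.n_loops
    dt = 1.0 / cfg.fs_hz
    n_steps = int(round(theta_total / (w * dt)))
    if n_steps < 2:
        raise ValueError("degenerate config: spiral spans fewer than 3 samples")
    t = np.arange(n_steps + 1) * dt

    if cfg.entropy_knob > 0:
        # Smooth random angular-speed modulation: low-pass filtered white
        # noise with unit SD, floored so the pen never moves backwards.
        noise = rng.standard_normal(n_steps + 1)
        smooth = gaussian_filter1d(noise, sigma=max(cfg.fs_hz * 0.05, 1.0))
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        w_inst = w * np.clip(1.0 + cfg.entropy_knob * smooth, 0.1, None)
        theta = np.concatenate(([0.0], np.cumsum(0.5 * (w_inst[1:] + w_inst[:-1]) * dt)))
        theta *= theta_total / theta[-1]
    else:
        theta = (theta_total / n_steps) * np.arange(n_steps + 1)

    r = cfg.spacing_cm * theta / (2.0 * np.pi)
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    if cfg.tremor_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=2)
        x = x + cfg.tremor_amp * np.sin(2 * np.pi * cfg.tremor_hz * t + phase[0])
        y = y + cfg.tremor_amp * np.sin(2 * np.pi * cfg.tremor_hz * t + phase[1])
    if cfg.jitter_sd > 0:
        x = x + rng.normal(0, cfg.jitter_sd, size=t.shape)
        y = y + rng.normal(0, cfg.jitter_sd, size=t.shape)
    if cfg.direction == "clockwise":
        # Mirror the finished trace so clockwise/counterclockwise draws from
        # the same seed are exact mirror images.
        y = -y

    return SpiralTrace(t=t, x=x, y=y, task=task, level=level,
                       repeat=repeat, subject=subject)


@dataclass(frozen=True)
class EffectSpec:
    """Cohort-level stimulation effects on spiral drawing.

    Per-subject speed gains are drawn from a normal distribution (truncated
    at zero); the entropy knob is set per level, defaulting to a drop from
    stimulation-off to any stimulation-on level with no further change --
    the pattern the velocity-entropy analysis is meant to detect.
    ``task_speed_factor`` makes self-paced drawing faster than traced.
    """

    speed_gain_mean: float = 0.15
    speed_gain_sd: float = 0.05
    entropy_knob_by_level: tuple[float, float, float, float] = (0.4, 0.25, 0.25, 0.25)
    task_speed_factor: float = 1.15  # self-paced relative to traced


def gen_cohort_spirals(n_subjects: int, cfg: SpiralGenConfig,
                       effect: EffectSpec | None = None,
                       seed: int | None = None) -> list[SpiralTrace]:
    """Generate 2 tasks x 4 levels x 5 repeats of spirals per subject.

    Fully reproducible from ``seed``; per-subject random effects on the
    velocity gain are drawn from the effect spec.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if effect is None:
        effect = EffectSpec()
    rng = np.random.default_rng(seed)
    traces: list[SpiralTrace] = []
    for s in range(n_subjects):
        subject = f"s{s + 1:02d}"
        gain = max(0.0, rng.normal(effect.speed_gain_mean, effect.speed_gain_sd))
        for task in TASKS:
            speed = cfg.base_angular_speed * (
                effect.task_speed_factor if task == "self_paced" else 1.0)
            for level in LEVELS:
                sub_cfg = replace(cfg, base_angular_speed=speed,
                                  level_speed_gain=gain,
                                  entropy_knob=effect.entropy_knob_by_level[level])
                for rep in range(1, 6):
                    traces.append(gen_spiral(sub_cfg, level, rng, task=task,
                                             repeat=rep, subject=subject))
    return traces


# ---------------------------------------------------------------------------
# MVAR network ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Oscillator:
    """Damped AR(2) resonance: complex-conjugate poles at radius ``damping``
    and angle 2*pi*f0/fs, giving a spectral peak at ``f0_hz``."""

    f0_hz: float
    damping: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")


@dataclass(frozen=True)
class Edge:
    """Directed coupling from ``source`` to ``target``.

    The coupling acts through a short FIR kernel starting at lag ``lag``
    whose gain at ``center_hz`` equals ``gain * level_gains[level]``. When
    ``stop_band`` is given, conjugate zero pairs are spread across it (plus a
    DC zero and a raised-cosine high-frequency taper), confining the coupling
    -- and therefore its level modulation -- to the edge's own band.
    """

    source: str
    target: str
    gain: float
    center_hz: float
    lag: int = 2
    stop_band: tuple[float, float] | None = None
    level_gains: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("edge lag must be >= 1")
        if not np.isfinite(self.gain):
            raise ValueError("edge gain must be finite")


def _edge_kernel(edge: Edge, fs_hz: float) -> np.ndarray:
    """FIR taps of an edge, normalized to unit gain at ``edge.center_hz``."""
    taps = np.array([1.0])
    if edge.stop_band is not None:
        lo, hi = edge.stop_band
        zero_freqs = [lo + frac * (hi - lo) for frac in (0.08, 0.5, 0.92)]
        # Guard zeros between the analysis range and Nyquist keep the
        # out-of-band kernel gain small (stability of the full network).
        guard_lo = max(hi, edge.center_hz) * 1.3
        zero_freqs += list(np.linspace(guard_lo, 0.47 * fs_hz, 4))
        for fz in zero_freqs:
            wz = 2 * np.pi * fz / fs_hz
            taps = np.convolve(taps, [1.0, -2.0 * np.cos(wz), 1.0])
        taps = np.convolve(taps, [1.0, -1.0])  # DC zero
        for _ in range(2):  # residual high-frequency taper (Nyquist zeros)
            taps = np.convolve(taps, [0.5, 0.5])
    wc = 2 * np.pi * edge.center_hz / fs_hz
    h0 = np.abs(np.sum(taps * np.exp(-1j * wc * np.arange(taps.size))))
    if h0 <= 0:
        raise ValueError("edge kernel vanishes at its own center frequency")
    return taps / h0


@dataclass
class NetworkSpec:
    """Region-of-interest network: per-ROI resonators plus directed edges.

    ``level_source_gain`` optionally scales each ROI's innovation SD per
    stimulation level, emulating level-dependent local power changes on top
    of the coupling modulation.
    """

    roi_labels: tuple[str, ...]
    oscillators: dict[str, Oscillator]
    edges: list[Edge] = field(default_factory=list)
    level_source_gain: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)
    fs_hz: float = 500.0
    innovation_sd: float = 1.0

    def __post_init__(self) -> None:
        self.roi_labels = tuple(self.roi_labels)
        missing = set(self.roi_labels) - set(self.oscillators)
        if missing:
            raise ValueError(f"no oscillator declared for ROIs {sorted(missing)}")
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in self.roi_labels:
                    raise ValueError(f"edge endpoint {end!r} is not a declared ROI")


def build_mvar_from_spec(spec: NetworkSpec, level: int) -> MVARModel:
    """Realize the network at one stimulation level as a stable MVAR model.

    Each ROI is a damped AR(2) resonator; each edge adds its FIR kernel,
    scaled by the edge's level gain, to the off-diagonal coefficients. The
    returned model is checked for stability.
    """
    if level not in LEVELS:
        raise ValueError(f"stimulation level must be 0..3, got {level}")
    k = len(spec.roi_labels)
    idx = {lab: i for i, lab in enumerate(spec.roi_labels)}

    p = 2
    kernels: list[tuple[Edge, np.ndarray]] = []
    for e in spec.edges:
        taps = _edge_kernel(e, spec.fs_hz)
        kernels.append((e, taps))
        p = max(p, e.lag + taps.size - 1)

    A = np.zeros((p, k, k))
    for lab, i in idx.items():
        osc = spec.oscillators[lab]
        w0 = 2 * np.pi * osc.f0_hz / spec.fs_hz
        A[0, i, i] = 2 * osc.damping * np.cos(w0)
        A[1, i, i] = -osc.damping**2
    for e, taps in kernels:
        g = e.gain * e.level_gains[level]
        A[e.lag - 1:e.lag - 1 + taps.size, idx[e.target], idx[e.source]] += g * taps

    sd = np.full(k, spec.innovation_sd)
    for lab, gains in spec.level_source_gain.items():
        sd[idx[lab]] *= gains[level]
    model = MVARModel(A=A, Sigma=np.diag(sd**2), fs_hz=spec.fs_hz,
                      labels=spec.roi_labels)
    if not model.is_stable():
        offenders = ", ".join(f"{e.source}->{e.target} (gain {e.gain})"
                              for e in spec.edges)
        raise ValueError(
            f"constructed MVAR is unstable (spectral radius "
            f"{model.spectral_radius():.3f}); reduce edge gains [{offenders}]")
    return model


def default_motor_network(modulate_source_gain: bool = True,
                          fs_hz: float = 500.0) -> NetworkSpec:
    """The stock 8-ROI motor network used throughout the package.

    High-beta (25 Hz) subthalamo-cortical edges STN<->M1 weaken with
    stimulation level; high-gamma (80 Hz) edges between M1 and the premotor
    areas (SMA, DPMC, VPMC) strengthen with level. The visual cortex is an
    isolated, level-invariant alpha resonator serving as a null reference.
    With ``modulate_source_gain`` the beta-dominated ROIs additionally lose
    and the gamma-dominated ROIs gain innovation drive across levels, so that
    local band power mirrors the couplings.
    """
    beta_mult = (1.0, 0.75, 0.5, 0.25)
    gamma_mult = (0.25, 0.5, 0.75, 1.0)
    osc = {
        "M1": Oscillator(25.0, 0.85),
        "SMA": Oscillator(80.0, 0.9),
        "preSMA": Oscillator(25.0, 0.9),
        "DPMC": Oscillator(80.0, 0.9),
        "VPMC": Oscillator(80.0, 0.9),
        "DLPFC": Oscillator(25.0, 0.9),
        "VC": Oscillator(10.0, 0.9),
        "STN": Oscillator(25.0, 0.85),
    }
    hb, hg = (21.0, 30.0), (61.0, 100.0)
    edges = [
        Edge("STN", "M1", 0.06, 25.0, stop_band=hg, level_gains=beta_mult),
        Edge("M1", "STN", 0.06, 25.0, stop_band=hg, level_gains=beta_mult),
    ]
    for pm in ("SMA", "DPMC", "VPMC"):
        edges.append(Edge(pm, "M1", 0.06, 80.0, stop_band=hb,
                          level_gains=gamma_mult))
        edges.append(Edge("M1", pm, 0.06, 80.0, stop_band=hb,
                          level_gains=gamma_mult))
    level_source_gain = {}
    if modulate_source_gain:
        down, up = (1.0, 0.9, 0.8, 0.7), (0.7, 0.8, 0.9, 1.0)
        level_source_gain = {"STN": down, "M1": down, "preSMA": down,
                             "DLPFC": down, "SMA": up, "DPMC": up, "VPMC": up}
    return NetworkSpec(roi_labels=ROI_LABELS, oscillators=osc, edges=edges,
                       level_source_gain=level_source_gain, fs_hz=fs_hz)


def _innovation_chol(Sigma: np.ndarray) -> np.ndarray:
    if np.allclose(Sigma, 0.0):
        return np.zeros_like(Sigma)
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(Sigma)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def simulate_mvar_ensemble(model: MVARModel, n_samples: int, seed: int | None,
                           n_realizations: int, burn_in: int | None = None
                           ) -> np.ndarray:
    """Simulate independent realizations jointly; returns (R, K, n_samples).

    The recursion starts from zeros and a burn-in of max(10*p, 200) samples
    is discarded so the retained stretch is approximately stationary.
    """
    if not model.is_stable():
        raise ValueError("refusing to simulate an unstable MVAR model")
    if n_samples < 1 or n_realizations < 1:
        raise ValueError("n_samples and n_realizations must be positive")
    p, k = model.p, model.k
    if n_samples <= 10 * p * k**2:
        warnings.warn(
            f"n_samples={n_samples} is small for K={k}, p={p}; coefficient "
            "recovery from this realization may be poor", stacklevel=2)
    if burn_in is None:
        burn_in = max(10 * p, 200)
    rng = np.random.default_rng(seed)
    chol = _innovation_chol(model.Sigma)
    # Newest-lag-first flattened coefficients: x_t = A_flat @ state + e_t
    a_flat = np.concatenate(list(model.A), axis=1)  # K x K*p
    state = np.zeros((p * k, n_realizations))
    out = np.empty((n_samples, k, n_realizations))
    total = burn_in + n_samples
    innov = chol @ rng.standard_normal((k, total * n_realizations))
    innov = innov.reshape(k, total, n_realizations)
    for t in range(total):
        x_t = a_flat @ state + innov[:, t, :]
        if t >= burn_in:
            out[t - burn_in] = x_t
        if p > 1:
            state[k:] = state[:-k]
        state[:k] = x_t
    return np.ascontiguousarray(out.transpose(2, 1, 0))


def simulate_mvar(model: MVARModel, n_samples: int,
                  seed: int | None = None) -> MultichannelRecording:
    """One stationary realization of the model as a source-space recording."""
    data = simulate_mvar_ensemble(model, n_samples, seed, 1)[0]
    return MultichannelRecording(data=data, fs_hz=model.fs_hz,
                                 labels=model.labels, space="source")


# ---------------------------------------------------------------------------
# Sensor projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModelSpec:
    """Sensor-array surrogate: lead-field mixing plus additive contaminants.

    The pulse rate default follows typical subthalamic stimulator settings
    (~130-135 Hz). ``dbs_artifact`` is (rate_hz, amplitude, duty).
    """

    n_sensors: int = 64
    leadfield_seed: int = 0
    sensor_noise_sd: float = 0.1
    line_noise_amp: float = 0.0
    line_hz: float = 50.0
    dbs_artifact: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")


def random_leadfield(n_sensors: int, source_labels: tuple[str, ...],
                     seed: int | None = None, smooth_sigma: float = 2.0,
                     max_retries: int = 5) -> LeadField:
    """Smooth random mixing matrix, column-normalized and full column rank.

    A Gaussian matrix smoothed along the sensor index mimics the spatial
    spread of volume conduction without any anatomy.
    """
    n_src = len(source_labels)
    if n_sensors < n_src:
        raise ValueError("need at least as many sensors as sources")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        m = rng.standard_normal((n_sensors, n_src))
        m = gaussian_filter1d(m, sigma=smooth_sigma, axis=0)
        m /= np.linalg.norm(m, axis=0, keepdims=True)
        if np.linalg.matrix_rank(m) == n_src:
            sensors = tuple(f"E{i + 1:02d}" for i in range(n_sensors))
            return LeadField(matrix=m, sensor_labels=sensors,
                             source_labels=source_labels)
    raise RuntimeError("failed to generate a full-rank lead field")


def _pulse_train(n: int, fs: float, rate_hz: float, amplitude: float,
                 duty: float) -> np.ndarray:
    t = np.arange(n) / fs
    phase = (t * rate_hz) % 1.0
    return amplitude * (phase < duty).astype(float)


def project_to_sensors(sources: MultichannelRecording,
                       sensor_spec: SensorModelSpec,
                       leadfield: LeadField | None = None,
                       seed: int | None = None
                       ) -> tuple[MultichannelRecording, LeadField]:
    """Mix source activity to sensors: L @ sources + noise + line + pulses."""
    if leadfield is None:
        leadfield = random_leadfield(sensor_spec.n_sensors, sources.labels,
                                     seed=sensor_spec.leadfield_seed)
    if leadfield.n_sources != sources.n_channels:
        raise ValueError("lead-field source count does not match recording")
    rng = np.random.default_rng(seed)
    data = leadfield.matrix @ sources.data
    n_sens, n = data.shape
    if sensor_spec.sensor_noise_sd > 0:
        data = data + rng.normal(0, sensor_spec.sensor_noise_sd, size=data.shape)
    if sensor_spec.line_noise_amp > 0:
        t = np.arange(n) / sources.fs_hz
        line = np.sin(2 * np.pi * sensor_spec.line_hz * t + rng.uniform(0, 2 * np.pi))
        gains = sensor_spec.line_noise_amp * rng.uniform(0.5, 1.5, size=n_sens)
        data = data + gains[:, None] * line[None, :]
    if sensor_spec.dbs_artifact is not None:
        rate, amp, duty = sensor_spec.dbs_artifact
        pulses = _pulse_train(n, sources.fs_hz, rate, amp, duty)
        topo = rng.uniform(0.5, 1.5, size=n_sens)
        data = data + topo[:, None] * pulses[None, :]
    rec = MultichannelRecording(data=data, fs_hz=sources.fs_hz,
                                labels=leadfield.sensor_labels, space="sensor")
    return rec, leadfield


# ---------------------------------------------------------------------------
# Feature-level cohort for the prediction stage
# ---------------------------------------------------------------------------

def gen_feature_cohort(n_subjects: int = 38, seed: int | None = None,
                       informative: dict[str, float] | None = None,
                       noise_sd: float = 0.3):
    """Per-subject ROI power-slope features plus a velocity-slope target.

    Returns ``(X, y)`` where ``X`` is an (n_subjects, 8) DataFrame of
    standardized high-beta power slopes (one column per ROI) and ``y`` the
    velocity slope. Only the ROIs named in ``informative`` (default M1 and
    DLPFC) carry signal; the default weights and noise give a ceiling
    R^2 of about 0.93 at the study's cohort size.
    """
    import pandas as pd

    if informative is None:
        informative = {"M1": 0.9, "DLPFC": 0.7}
    unknown = set(informative) - set(ROI_LABELS)
    if unknown:
        raise ValueError(f"unknown ROIs in effect spec: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n_subjects, len(ROI_LABELS))),
                     columns=list(ROI_LABELS))
    y = rng.normal(0, noise_sd, size=n_subjects)
    for roi, beta in informative.items():
        y = y + beta * X[roi].to_numpy()
    return X, np.asarray(y)


def connectivity_subnetwork(spec: NetworkSpec) -> tuple[str, ...]:
    """ROIs of the spec that enter the directed-connectivity analysis."""
    return tuple(r for r in spec.roi_labels if r in CONNECTIVITY_ROIS)
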