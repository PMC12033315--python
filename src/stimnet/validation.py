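"""Ground-truth validation experiments.

Each function re-derives one of the package's verifiable claims from scratch
-- simulating from the generator, running the corresponding analysis stage,
and measuring the result -- and returns plain floats. The test suite asserts
on these outputs at fixed tolerances and the reproduction script reports
them.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import synthetic
from .connectivity import MVAR, band_mean_gpdc, fit_mvar, gpdc, gpdc_surrogate_null
from .containers import CONNECTIVITY_ROIS, DEFAULT_BANDS, LEVELS, MVARModel
from .kinematics import sample_entropy, tangential_velocity
from .predict import cv_r2, exact_shapley, fit_svr_rbf, rank_features
from .spectral import band_power, welch_psd
from .stats import rm_anova_level, wilcoxon_signed_rank
from .synthetic import (
    NetworkSpec,
    SensorModelSpec,
    SpiralGenConfig,
    build_mvar_from_spec,
    gen_feature_cohort,
    gen_spiral,
    project_to_sensors,
    simulate_mvar,
    simulate_mvar_ensemble,
)

__all__ = [
    "motor_connectivity_subnetwork",
    "gpdc_normalization_check",
    "gpdc_bivariate_hand_value",
    "mvar_recovery",
    "directionality_vs_surrogate",
    "connectivity_direction_experiment",
    "velocity_closed_form_error",
    "welch_power_checks",
    "lcmv_checks",
    "shapley_checks",
    "prediction_recovery",
    "rm_anova_type1_rate",
]


def motor_connectivity_subnetwork() -> NetworkSpec:
    """The 5-ROI subnetwork entering the gPDC analysis, couplings only.

    All directed edges of the stock motor network live within
    {M1, SMA, DPMC, VPMC, STN}, so this subnetwork is an exact MVAR process;
    local source-gain modulation is off so that only the couplings change
    with stimulation level.
    """
    net = synthetic.default_motor_network(modulate_source_gain=False)
    return NetworkSpec(
        roi_labels=CONNECTIVITY_ROIS,
        oscillators={r: net.oscillators[r] for r in CONNECTIVITY_ROIS},
        edges=net.edges,
        fs_hz=net.fs_hz,
    )


def gpdc_normalization_check(seed: int = 0, n_models: int = 20) -> float:
    """Max deviation of sum_i |pi_ij|^2 from 1 over random stable models."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    models = []
    while len(models) < n_models:
        k = int(rng.integers(2, 6))
        p = int(rng.integers(1, 4))
        a = rng.normal(0, 0.15, size=(p, k, k))
        sig = np.diag(rng.uniform(0.3, 3.0, size=k))
        model = MVARModel(A=a, Sigma=sig, fs_hz=500.0)
        if model.is_stable(0.97):
            models.append(model)
    for lv in LEVELS:
        models.append(build_mvar_from_spec(motor_connectivity_subnetwork(), lv))
    for model in models:
        spec = gpdc(model)
        col = np.sum(spec.pi_abs**2, axis=0)
        worst = max(worst, float(np.abs(col - 1.0).max()))
    return worst


def gpdc_bivariate_hand_value() -> dict[str, float]:
    """Bivariate model with one lag-1 coupling, evaluated at f=0.

    Hand evaluation: Abar(0) = [[0.5, -0.4], [0, 0.5]], unit innovations, so
    |pi_12(0)| = 0.4 / sqrt(0.41) = 0.62469... and |pi_21(0)| = 0.
    """
    a = np.array([[[0.5, 0.4], [0.0, 0.5]]])
    model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0)
    spec = gpdc(model, freqs=np.array([0.0]))
    return {
        "pi_12_f0": float(spec.pi_abs[0, 1, 0]),
        "pi_21_f0": float(spec.pi_abs[1, 0, 0]),
        "hand_value": 0.4 / np.sqrt(0.41),
    }


def _random_stable_model(seed: int, k: int = 5, p: int = 3,
                         fs: float = 500.0) -> MVARModel:
    rng = np.random.default_rng(seed)
    for _ in range(200):
        a = rng.normal(0, 0.12, size=(p, k, k))
        a[0] += 0.3 * np.eye(k)
        model = MVARModel(A=a, Sigma=np.eye(k), fs_hz=fs)
        if model.spectral_radius() < 0.95:
            return model
    raise RuntimeError("no stable draw")


def mvar_recovery(seed: int = 0, n_samples: int = 20_000) -> float:
    """Max absolute coefficient error recovering a K=5, p=3 model."""
    truth = _random_stable_model(seed)
    rec = simulate_mvar(truth, n_samples, seed=seed + 1)
    fitted = fit_mvar(rec, order=truth.p)
    return float(np.abs(fitted.A - truth.A).max())


def directionality_vs_surrogate(seed: int = 0, n_samples: int = 20_000,
                                n_surrogates: int = 100) -> dict[str, float]:
    """Unidirectional coupling vs the phase-randomized surrogate null."""
    a = np.zeros((2, 2, 2))
    a[0] = [[0.5, 0.0], [0.0, 0.5]]
    a[1, 0, 1] = 0.35  # src -> tgt at lag 2
    model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=500.0, labels=("tgt", "src"))
    rec = simulate_mvar(model, n_samples, seed=seed)
    spec = gpdc(fit_mvar(rec, order=2))
    band = DEFAULT_BANDS["high_beta"]
    fwd = float(band_mean_gpdc(spec, band, [("src", "tgt")])["gpdc"][0])
    rev = float(band_mean_gpdc(spec, band, [("tgt", "src")])["gpdc"][0])
    null = gpdc_surrogate_null(rec, band, [("tgt", "src")], order=2,
                               n_surrogates=n_surrogates, seed=seed + 1)
    return {"forward": fwd, "reverse": rev,
            "null_95": null[("tgt", "src")]}


def connectivity_direction_experiment(n_runs: int = 100,
                                      n_samples: int = 10_000,
                                      seed: int = 0) -> dict[str, float]:
    """Monte-Carlo reproduction of the stimulation-level direction of effect.

    For each run and level the 5-ROI network is simulated, a joint MVAR is
    fitted at the generator's order, and band-mean gPDC is extracted for the
    high-beta STN->M1 edge (ground truth: decreasing with level), the
    high-gamma premotor->M1 edges (increasing), and the high-gamma STN->M1
    pair (unaffected by construction).
    """
    net = motor_connectivity_subnetwork()
    models = {lv: build_mvar_from_spec(net, lv) for lv in LEVELS}
    p = models[0].p
    hb, hg = DEFAULT_BANDS["high_beta"], DEFAULT_BANDS["high_gamma"]
    premotor_pairs = [("SMA", "M1"), ("DPMC", "M1"), ("VPMC", "M1")]
    hb_stn = np.empty((n_runs, 4))
    hg_stn = np.empty((n_runs, 4))
    hg_prem = np.empty((n_runs, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lv in LEVELS:
            ens = simulate_mvar_ensemble(models[lv], n_samples,
                                         seed=seed * 7919 + lv, n_realizations=n_runs)
            for r in range(n_runs):
                est = MVAR(order=p).fit(ens[r].T)
                spec = gpdc(est.to_model(net.fs_hz, net.roi_labels))
                hb_stn[r, lv] = band_mean_gpdc(
                    spec, hb, [("STN", "M1")])["gpdc"][0]
                hg_stn[r, lv] = band_mean_gpdc(
                    spec, hg, [("STN", "M1")])["gpdc"][0]
                hg_prem[r, lv] = band_mean_gpdc(
                    spec, hg, premotor_pairs)["gpdc"].mean()
    lv_idx = np.arange(4.0)
    slope = lambda m: np.polyfit(lv_idx, m.T, 1)[0]  # noqa: E731
    hg_stn_slopes = slope(hg_stn)
    hg_prem_slopes = slope(hg_prem)
    return {
        "frac_high_beta_stn_m1_monotone_decreasing": float(
            np.mean(np.all(np.diff(hb_stn, axis=1) < 0, axis=1))),
        "frac_high_gamma_premotor_m1_increasing": float(
            np.mean(hg_prem_slopes > 0)),
        "high_gamma_stn_m1_mean_slope": float(hg_stn_slopes.mean()),
        "high_gamma_stn_m1_slope_sd": float(hg_stn_slopes.std(ddof=1)),
        "high_gamma_premotor_m1_mean_slope": float(hg_prem_slopes.mean()),
        "high_beta_stn_m1_level_means": hb_stn.mean(axis=0).tolist(),
        "n_runs": n_runs,
    }


def velocity_closed_form_error() -> float:
    """Max relative error of the numeric tangential velocity against
    v(t) = (b / 2 pi) w^2 t on a noise-free spiral, beyond the first 3
    samples."""
    cfg = SpiralGenConfig(base_angular_speed=2 * np.pi * 0.1,
                          level_speed_gain=0.0)
    tr = gen_spiral(cfg, 0)
    v = tangential_velocity(tr)
    expected = cfg.spacing_cm / (2 * np.pi) * cfg.base_angular_speed**2 * tr.t
    return float(np.max(np.abs(v[3:] - expected[3:]) / expected[3:]))


def sampen_oracle_max_deviation(seed: int = 0, n: int = 300) -> float:
    """Max |SampEn - exhaustive oracle| over a set of length-n series."""
    from math import log

    rng = np.random.default_rng(seed)
    series = [
        rng.standard_normal(n),
        np.sin(np.arange(n) * 0.21) + 0.1 * rng.standard_normal(n),
        np.cumsum(rng.standard_normal(n)),
    ]
    worst = 0.0
    for x in series:
        got = sample_entropy(x, m=2, r_frac=0.2)
        r = 0.2 * x.std()
        nt = n - 2
        a = b = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i] - x[j]), abs(x[i + 1] - x[j + 1])) <= r:
                    b += 1
                    if abs(x[i + 2] - x[j + 2]) <= r:
                        a += 1
        worst = max(worst, abs(got - (-log(a / b))))
    return worst


def welch_power_checks(seed: int = 0) -> dict[str, float]:
    """Sinusoid band-power recovery and white-noise Parseval consistency."""
    fs = 500.0
    t = np.arange(100_000) / fs
    psd = welch_psd(np.sin(2 * np.pi * 25.0 * t), fs=fs)
    hb = band_power(psd, DEFAULT_BANDS["high_beta"])
    others = sum(band_power(psd, DEFAULT_BANDS[b])
                 for b in ("low_beta", "low_gamma", "high_gamma"))
    x = np.random.default_rng(seed).standard_normal(100_000)
    wpsd = welch_psd(x, fs=fs)
    return {
        "sine_high_beta_power": float(hb),
        "sine_other_band_power": float(others),
        "white_noise_psd_integral": float(np.trapezoid(wpsd.density, wpsd.freqs)),
        "white_noise_variance": float(x.var()),
    }


def lcmv_checks(seed: int = 0) -> dict[str, float]:
    """Unit gain, minimum-variance optimality, and source round trip."""
    from .sources import estimate_covariance, extract_sources, lcmv_filters

    rng = np.random.default_rng(seed)
    # Two uncorrelated band-limited sources mixed to 16 sensors.
    rho, fs = 0.9, 500.0
    a = np.zeros((2, 2, 2))
    for i, f0 in enumerate((20.0, 45.0)):
        w0 = 2 * np.pi * f0 / fs
        a[0, i, i] = 2 * rho * np.cos(w0)
        a[1, i, i] = -rho**2
    model = MVARModel(A=a, Sigma=np.eye(2), fs_hz=fs, labels=("s1", "s2"))
    src = simulate_mvar(model, 20_000, seed=seed + 1)
    spec = SensorModelSpec(n_sensors=16, sensor_noise_sd=0.05,
                           leadfield_seed=seed + 2)
    sens, lf = project_to_sensors(src, spec, seed=seed + 3)
    cov = estimate_covariance(sens, shrinkage=0.01)
    filt = lcmv_filters(lf, cov)
    gain_dev = float(np.abs(np.diag(filt.weights @ lf.matrix) - 1.0).max())
    rec_src = extract_sources(sens, filt)
    corr = min(abs(float(np.corrcoef(rec_src.data[i], src.data[i])[0, 1]))
               for i in range(2))
    # Minimum variance against 1000 random unit-gain filters.
    w0 = filt.weights[0]
    l0 = lf.matrix[:, 0]
    w_var = w0 @ cov @ w0
    margin = np.inf
    for _ in range(1000):
        v = rng.standard_normal(lf.n_sensors)
        v = v / (v @ l0)
        margin = min(margin, float(v @ cov @ v - w_var))
    return {"unit_gain_max_dev": gain_dev, "roundtrip_min_corr": corr,
            "min_variance_worst_margin": margin}


def shapley_checks(seed: int = 0) -> dict[str, float]:
    """Exact-Shapley axioms at d=8 and the linear-model closed form."""
    rng = np.random.default_rng(seed)
    d = 8
    beta = rng.standard_normal(d)
    x = rng.standard_normal((15, d))
    attr = exact_shapley(lambda z: z @ beta, x)
    linear_dev = float(np.abs(attr.phi - beta * (x - x.mean(0))).max())
    efficiency_dev = float(np.abs(attr.phi.sum(1)
                                  - (attr.predictions - attr.baseline)).max())
    x2 = x.copy()
    x2[:, 1] = x2[:, 0]
    attr2 = exact_shapley(lambda z: z[:, 0] + z[:, 1] + z @ np.zeros(d), x2)
    symmetry_dev = float(np.abs(attr2.phi[:, 0] - attr2.phi[:, 1]).max())
    attr3 = exact_shapley(lambda z: np.sin(z[:, 0]), x)
    dummy_dev = float(np.abs(attr3.phi[:, 1:]).max())
    return {"linear_closed_form_dev": linear_dev,
            "efficiency_dev": efficiency_dev,
            "symmetry_dev": symmetry_dev,
            "dummy_dev": dummy_dev}


def prediction_recovery(n_seeds: int = 50, seed: int = 0,
                        n_subjects: int = 38) -> dict[str, float]:
    """Recovery of the velocity-slope prediction on the feature cohort.

    Signal is confined to the M1 and DLPFC high-beta power slopes; success
    per seed requires repeated-CV R^2 > 0.5 and M1 among the top-2 features
    by mean |SHAP|.
    """
    r2s, hits_r2, hits_m1, hits_joint = [], 0, 0, 0
    for s in range(n_seeds):
        X, y = gen_feature_cohort(n_subjects, seed=seed * 100_003 + s)
        r2_mean, _, _ = cv_r2(X, y, seed=seed + s)
        model = fit_svr_rbf(X, y)
        ranked = rank_features(exact_shapley(model, X))
        top2 = set(ranked["feature"].iloc[:2])
        r2s.append(r2_mean)
        hits_r2 += r2_mean > 0.5
        hits_m1 += "M1" in top2
        hits_joint += (r2_mean > 0.5) and ("M1" in top2)
    X, y = gen_feature_cohort(n_subjects, seed=seed + 55_001)
    y_perm = np.random.default_rng(seed + 1).permutation(y)
    null_mean, null_sd, _ = cv_r2(X, y_perm, n_repeats=20, seed=seed)
    return {
        "frac_r2_above_0p5": hits_r2 / n_seeds,
        "frac_m1_top_ranked": hits_m1 / n_seeds,
        "frac_joint_success": hits_joint / n_seeds,
        "cv_r2_mean": float(np.mean(r2s)),
        "permuted_null_r2_mean": null_mean,
        "permuted_null_r2_sd": null_sd,
        "n_seeds": n_seeds,
    }


def rm_anova_type1_rate(n_reps: int = 1000, n_subjects: int = 38,
                        seed: int = 0, alpha: float = 0.05) -> float:
    """Empirical rejection rate of the RM-ANOVA under the global null."""
    rng = np.random.default_rng(seed)
    rejections = sum(
        rm_anova_level(rng.standard_normal((n_subjects, 4))).p < alpha
        for _ in range(n_reps))
    return rejections / n_reps


def wilcoxon_exact_check(seed: int = 0) -> dict[str, float]:
    """Exact Wilcoxon p at n=10 against full sign enumeration."""
    from itertools import product

    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(10)
    y = rng.standard_normal(10)
    _, p = wilcoxon_signed_rank(x, y)
    d = (x - y)[(x - y) != 0]
    ranks = rankdata(np.abs(d))
    mean_w = d.size * (d.size + 1) / 4
    dev = abs(ranks[d > 0].sum() - mean_w)
    count = sum(
        1 for signs in product([0, 1], repeat=d.size)
        if abs(sum(r for r, s in zip(ranks, signs) if s) - mean_w) >= dev - 1e-9)
    return {"p_exact": float(p), "p_enumerated": count / 2**d.size}
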