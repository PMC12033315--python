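"""Generator ground truths: spiral closed forms, MVAR construction and
simulation, sensor projection."""

import numpy as np
import pytest
from scipy.signal import welch

from stimnet import preprocess, synthetic
from stimnet.containers import MVARModel
from stimnet.kinematics import tangential_velocity
from stimnet.synthetic import (
    Edge,
    NetworkSpec,
    Oscillator,
    SensorModelSpec,
    SpiralGenConfig,
    build_mvar_from_spec,
    gen_cohort_spirals,
    gen_spiral,
    project_to_sensors,
    simulate_mvar,
)


class TestGenSpiral:
    def test_noise_free_final_radius_exact(self):
        cfg = SpiralGenConfig(jitter_sd=0, entropy_knob=0, level_speed_gain=0)
        tr = gen_spiral(cfg, level=0)
        r_final = np.hypot(tr.x[-1], tr.y[-1])
        assert r_final == pytest.approx(cfg.spacing_cm * cfg.n_loops, abs=1e-12)

    def test_radius_monotone_and_starts_at_center(self):
        tr = gen_spiral(SpiralGenConfig(), level=1)
        r = np.hypot(tr.x, tr.y)
        assert r[0] == 0.0
        assert np.all(np.diff(r) >= -1e-12)

    def test_velocity_slope_matches_imposed_gain(self):
        # Mean velocity is linear in angular speed: slope vs level must
        # reproduce the generator's analytic profile.
        cfg = SpiralGenConfig(jitter_sd=0, entropy_knob=0, level_speed_gain=0.2)
        means, truth = [], []
        for level in range(4):
            reps = [tangential_velocity(gen_spiral(cfg, level)).mean()
                    for _ in range(5)]
            means.append(np.mean(reps))
            truth.append(synthetic.analytic_mean_speed(cfg, level))
        fit = np.polyfit(np.arange(4), means, 1)[0]
        expected = np.polyfit(np.arange(4), truth, 1)[0]
        assert fit == pytest.approx(expected, rel=0.05)
        assert fit > 0

    def test_directions_are_mirror_images(self):
        cc = gen_spiral(SpiralGenConfig(seed=3, jitter_sd=0.02), 1)
        cw = gen_spiral(SpiralGenConfig(seed=3, jitter_sd=0.02,
                                        direction="clockwise"), 1)
        assert np.allclose(cc.x, cw.x)
        assert np.allclose(cc.y, -cw.y)

    @pytest.mark.parametrize("kwargs", [
        {"n_loops": 0}, {"fs_hz": 0.0}, {"spacing_cm": -1.0},
    ])
    def test_degenerate_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpiralGenConfig(**kwargs)

    def test_entropy_knob_raises_velocity_irregularity(self):
        from stimnet.kinematics import sample_entropy

        smooth = gen_spiral(SpiralGenConfig(seed=0, entropy_knob=0.0), 1)
        rough = gen_spiral(SpiralGenConfig(seed=0, entropy_knob=0.5), 1)
        se_smooth = sample_entropy(tangential_velocity(smooth))
        se_rough = sample_entropy(tangential_velocity(rough))
        assert se_rough > se_smooth


class TestCohort:
    def test_counts(self):
        traces = gen_cohort_spirals(3, SpiralGenConfig(), seed=0)
        assert len(traces) == 3 * 2 * 4 * 5
        one = [t for t in traces
               if (t.subject, t.task, t.level) == ("s01", "traced", 2)]
        assert sorted(t.repeat for t in one) == [1, 2, 3, 4, 5]

    def test_seed_reproducibility(self):
        a = gen_cohort_spirals(2, SpiralGenConfig(jitter_sd=0.02), seed=42)
        b = gen_cohort_spirals(2, SpiralGenConfig(jitter_sd=0.02), seed=42)
        assert all(np.array_equal(ta.x, tb.x) and np.array_equal(ta.y, tb.y)
                   for ta, tb in zip(a, b))

    def test_null_effect_slopes_center_at_zero(self):
        # With zero between-level gain the fitted velocity slopes must be
        # centered at zero over subjects.
        from stimnet.kinematics import slope_across_levels

        effect = synthetic.EffectSpec(speed_gain_mean=0.0, speed_gain_sd=0.0,
                                      entropy_knob_by_level=(0.3,) * 4)
        traces = gen_cohort_spirals(12, SpiralGenConfig(jitter_sd=0.01),
                                    effect=effect, seed=9)
        slopes = []
        for s in {t.subject for t in traces}:
            vals = {}
            for lv in range(4):
                grp = [t for t in traces
                       if (t.subject, t.task, t.level) == (s, "self_paced", lv)]
                vals[lv] = np.mean([tangential_velocity(t).mean() for t in grp])
            slopes.append(slope_across_levels(vals).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 2 * se + 1e-12


class TestBuildMVAR:
    def test_no_edges_gives_block_diagonal(self):
        spec = NetworkSpec(roi_labels=("a", "b"),
                           oscillators={"a": Oscillator(20.0),
                                        "b": Oscillator(40.0)})
        model = build_mvar_from_spec(spec, 0)
        off = model.A[:, ~np.eye(2, dtype=bool)]
        assert np.all(off == 0)

    def test_resonator_peak_at_center_frequency(self):
        # AR(2) poles at radius rho, angle 2*pi*f0/fs -> PSD argmax at f0.
        f0, fs, rho = 25.0, 500.0, 0.97
        spec = NetworkSpec(roi_labels=("a",),
                           oscillators={"a": Oscillator(f0, rho)}, fs_hz=fs)
        model = build_mvar_from_spec(spec, 0)
        freqs = np.arange(1.0, 250.0, 0.1)
        abar = np.abs(1 - model.A[0, 0, 0] * np.exp(-2j * np.pi * freqs / fs)
                      - model.A[1, 0, 0] * np.exp(-4j * np.pi * freqs / fs))
        psd = 1.0 / abar**2
        assert abs(freqs[np.argmax(psd)] - f0) < 1.0

    def test_doubling_edge_gain_increases_gpdc_at_center(self):
        from stimnet.connectivity import gpdc

        def make(gain):
            spec = NetworkSpec(
                roi_labels=("src", "dst"),
                oscillators={"src": Oscillator(25.0), "dst": Oscillator(25.0)},
                edges=[Edge("src", "dst", gain, 25.0)])
            return build_mvar_from_spec(spec, 0)

        freqs = np.array([25.0])
        lo = gpdc(make(0.1), freqs).pi_abs[1, 0, 0]
        hi = gpdc(make(0.2), freqs).pi_abs[1, 0, 0]
        assert hi > lo

    def test_unstable_construction_names_edges(self):
        spec = NetworkSpec(
            roi_labels=("a", "b"),
            oscillators={"a": Oscillator(25.0, 0.99), "b": Oscillator(25.0, 0.99)},
            edges=[Edge("a", "b", 2.0, 25.0), Edge("b", "a", 2.0, 25.0)])
        with pytest.raises(ValueError, match="unstable"):
            build_mvar_from_spec(spec, 0)

    def test_level_modulation_scales_edge(self):
        spec = NetworkSpec(
            roi_labels=("a", "b"),
            oscillators={"a": Oscillator(25.0), "b": Oscillator(25.0)},
            edges=[Edge("a", "b", 0.1, 25.0, level_gains=(1.0, 0.5, 0.25, 0.1))])
        m0 = build_mvar_from_spec(spec, 0)
        m1 = build_mvar_from_spec(spec, 1)
        assert np.allclose(m1.A[:, 1, 0], 0.5 * m0.A[:, 1, 0])


class TestSimulateMVAR:
    def test_ar1_variance_closed_form(self):
        # Var of AR(1) with a=0.5, sigma^2=1 is 1/(1-0.25).
        model = MVARModel(A=np.array([[[0.5]]]), Sigma=np.eye(1), fs_hz=100.0)
        rec = simulate_mvar(model, 100_000, seed=0)
        assert rec.data.var() == pytest.approx(1 / 0.75, rel=0.03)

    def test_zero_innovations_give_zero_output(self):
        model = MVARModel(A=np.array([[[0.5]]]), Sigma=np.zeros((1, 1)),
                          fs_hz=100.0)
        rec = simulate_mvar(model, 500, seed=1)
        assert np.all(rec.data == 0)

    def test_seed_determinism(self):
        model = MVARModel(A=np.array([[[0.5]]]), Sigma=np.eye(1), fs_hz=100.0)
        a = simulate_mvar(model, 1000, seed=5)
        b = simulate_mvar(model, 1000, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_refuses_unstable_model(self):
        model = MVARModel(A=np.array([[[1.05]]]), Sigma=np.eye(1), fs_hz=100.0)
        with pytest.raises(ValueError, match="unstable"):
            simulate_mvar(model, 1000, seed=0)

    def test_ensemble_matches_singleton_layout(self):
        model = MVARModel(A=np.array([[[0.5, 0.1], [0.0, 0.3]]]),
                          Sigma=np.eye(2), fs_hz=100.0)
        ens = synthetic.simulate_mvar_ensemble(model, 400, seed=3,
                                               n_realizations=4)
        assert ens.shape == (4, 2, 400)
        # realizations differ
        assert not np.allclose(ens[0], ens[1])


class TestProjectToSensors:
    def _sources(self, seed=0, n=4000, fs=500.0):
        model = MVARModel(A=0.4 * np.eye(2)[None], Sigma=np.eye(2), fs_hz=fs)
        return simulate_mvar(model, n, seed=seed)

    def test_identity_padded_leadfield_copies_sources(self):
        src = self._sources()
        k = src.n_channels
        from stimnet.containers import LeadField

        mat = np.vstack([np.eye(k), np.zeros((3, k))])
        lf = LeadField(matrix=mat,
                       sensor_labels=tuple(f"E{i}" for i in range(k + 3)),
                       source_labels=src.labels)
        spec = SensorModelSpec(n_sensors=k + 3, sensor_noise_sd=0.0)
        sens, _ = project_to_sensors(src, spec, leadfield=lf, seed=0)
        assert np.allclose(sens.data[:k], src.data)

    def test_dbs_artifact_adds_spectral_peak(self):
        src = self._sources(n=20_000)
        spec = SensorModelSpec(n_sensors=8, sensor_noise_sd=0.01,
                               dbs_artifact=(130.0, 5.0, 0.2))
        sens, _ = project_to_sensors(src, spec, seed=1)
        f, p_sens = welch(sens.data[0], fs=src.fs_hz, nperseg=2048)
        _, p_src = welch(src.data[0], fs=src.fs_hz, nperseg=2048)
        at_130 = np.argmin(np.abs(f - 130.0))
        neighborhood = (np.abs(f - 130) > 5) & (np.abs(f - 130) < 20)
        assert p_sens[at_130] > 10 * p_sens[neighborhood].mean()
        assert p_src[at_130] < 10 * p_src[neighborhood].mean()

    def test_line_noise_removed_by_notch_roundtrip(self):
        src = self._sources(n=20_000)
        spec = SensorModelSpec(n_sensors=8, sensor_noise_sd=0.05,
                               line_noise_amp=2.0)
        sens, _ = project_to_sensors(src, spec, seed=2)
        clean = preprocess.notch(sens, freqs=(50.0,))
        f, p_before = welch(sens.data[0], fs=src.fs_hz, nperseg=4096)
        _, p_after = welch(clean.data[0], fs=src.fs_hz, nperseg=4096)
        at_50 = np.argmin(np.abs(f - 50.0))
        assert p_after[at_50] < 1e-2 * p_before[at_50]

    def test_leadfield_full_rank_and_unit_columns(self):
        lf = synthetic.random_leadfield(16, tuple("abcde"), seed=0)
        assert np.linalg.matrix_rank(lf.matrix) == 5
        assert np.allclose(np.linalg.norm(lf.matrix, axis=0), 1.0)
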