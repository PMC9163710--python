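"""Synthetic cohort generator: phase integration, waveforms, cohort assembly."""
import numpy as np
import pytest

from nirscouple.errors import InvalidArgumentError
from nirscouple.phases import PhaseSeries
from nirscouple.synthetic import (
    ArtifactSpec,
    CouplingSpec,
    DEFAULT_PROFILES,
    GroupProfile,
    OscillatorSpec,
    _inject_artifacts,
    moca_band,
    simulate_cohort,
    simulate_phase_pair,
    simulate_subject,
    synthesize_recording,
)


class TestSimulatePhasePair:
    def test_zero_coupling_zero_noise_gives_linear_phase(self):
        a = OscillatorSpec(1.0, 0.0)
        b = OscillatorSpec(0.1, 0.0)
        pa, pb = simulate_phase_pair(a, b, None, duration=10, step=0.01, seed=0)
        t = pa.times
        np.testing.assert_allclose(pa.phase, 2 * np.pi * t, atol=1e-9)
        np.testing.assert_allclose(pb.phase, 2 * np.pi * 0.1 * t, atol=1e-9)

    def test_strong_sine_coupling_phase_locks(self):
        # Adler equation: psi' = -eps*sin(psi) has a stable fixed point
        a = OscillatorSpec(1.0, 0.0)
        b = OscillatorSpec(1.0, 0.0)
        cpl = CouplingSpec(("a", "b"), {(1, -1, "sin"): 3.0})
        pa, pb = simulate_phase_pair(a, b, cpl, duration=60, step=0.01,
                                     seed=0, phi0=(0.0, 2.0))
        psi = pa.phase - pb.phase
        tail = psi[-500:]
        assert np.ptp(tail) < 1e-6

    def test_least_squares_recovers_generative_sine_coefficient(self):
        # independent OLS oracle on the generative model, not the package's DBI
        a = OscillatorSpec(1.1, 0.01)
        b = OscillatorSpec(0.1, 0.01)
        cpl = CouplingSpec(("a", "b"), {(1, 0, "sin"): 0.3})
        pa, pb = simulate_phase_pair(a, b, cpl, duration=900, step=0.05, seed=7)
        h = 0.05
        dphi_b = np.diff(pb.phase) / h
        mid_a = 0.5 * (pa.phase[1:] + pa.phase[:-1])
        X = np.column_stack([np.ones_like(mid_a), np.sin(mid_a), np.cos(mid_a)])
        coef, *_ = np.linalg.lstsq(X, dphi_b, rcond=None)
        assert abs(coef[1] - 0.3) < 0.05

    def test_same_seed_identical_output(self):
        a = OscillatorSpec(1.1, 0.05)
        b = OscillatorSpec(0.1, 0.02)
        cpl = CouplingSpec(("a", "b"), {(1, 0, "sin"): 0.2})
        r1 = simulate_phase_pair(a, b, cpl, 60, 0.05, seed=5)
        r2 = simulate_phase_pair(a, b, cpl, 60, 0.05, seed=5)
        np.testing.assert_array_equal(r1[0].phase, r2[0].phase)
        np.testing.assert_array_equal(r1[1].phase, r2[1].phase)

    @pytest.mark.parametrize("duration,step", [(0, 0.05), (60, -1), (10, 0.05)])
    def test_invalid_arguments_rejected(self, duration, step):
        a = OscillatorSpec(1.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            simulate_phase_pair(a, a, None, duration, step, seed=0)

    def test_unknown_oscillator_in_coupling_rejected(self):
        a = OscillatorSpec(1.0, 0.0)
        cpl = CouplingSpec(("a", "c"), {(1, 0, "sin"): 0.1})
        with pytest.raises(InvalidArgumentError):
            simulate_phase_pair(a, a, cpl, 60, 0.01, seed=0)


def _trivial_phases(duration=200.0, rate=20.0):
    t = np.arange(int(duration * rate)) / rate
    mk = lambda f: PhaseSeries(2 * np.pi * f * t, rate)
    return {
        "cardiac": (mk(1.1), OscillatorSpec(1.1, 0.0, amplitude=20.0)),
        "VLF_L": (mk(0.04), OscillatorSpec(0.04, 0.0, amplitude=1.0)),
        "LF_L": (mk(0.1), OscillatorSpec(0.1, 0.0, amplitude=0.8)),
        "VLF_R": (mk(0.04), OscillatorSpec(0.04, 0.0, amplitude=1.0)),
        "LF_R": (mk(0.1), OscillatorSpec(0.1, 0.0, amplitude=0.8)),
    }


class TestSynthesizeRecording:
    def test_clean_signals_reproduce_drawn_toi_exactly(self):
        group = DEFAULT_PROFILES["NC"]
        rec, drawn = synthesize_recording(
            _trivial_phases(), group, ArtifactSpec(0, 0, 0, 0), seed=3,
            nirs_noise_sd=0.0, abp_noise_sd=0.0,
        )
        for side in ("L", "R"):
            o2 = rec.channels[f"O2Hb_{side}"].values.mean()
            hh = rec.channels[f"HHb_{side}"].values.mean()
            toi = 100 * o2 / (o2 + hh)
            assert toi == pytest.approx(drawn[f"toi_{side}"], abs=1e-9)

    def test_abp_sample_count_for_15_min_at_1000_hz(self):
        rec, _ = synthesize_recording(_trivial_phases(duration=900.0),
                                      DEFAULT_PROFILES["NC"],
                                      ArtifactSpec(0, 0, 0, 0), seed=0)
        assert rec.channels["ABP"].n_samples == 900_000
        assert rec.channels["O2Hb_L"].n_samples == 18_000

    def test_missing_component_rejected(self):
        phases = _trivial_phases()
        del phases["VLF_R"]
        with pytest.raises(InvalidArgumentError):
            synthesize_recording(phases, DEFAULT_PROFILES["NC"],
                                 ArtifactSpec(), seed=0)

    def test_injected_spike_count_matches_direct_count(self):
        # oracle: count the samples the injection actually touched
        rng = np.random.default_rng(11)
        x = np.zeros(18_000)
        spec = ArtifactSpec(spike_rate=2.0, spike_amplitude_sd=3.0,
                            motion_rate=0.0, motion_step_sd=0.0)
        _, n_spk, n_mot = _inject_artifacts(x, 20.0, spec, rng)
        assert n_mot == 0
        touched = np.count_nonzero(x)
        assert abs(touched - n_spk) <= 1  # rare index collision tolerated
        assert 10 <= n_spk <= 60  # Poisson(30)

    def test_spike_count_expectation_over_seeds(self):
        spec = ArtifactSpec(spike_rate=2.0, spike_amplitude_sd=3.0,
                            motion_rate=0.0, motion_step_sd=0.0)
        counts = []
        for s in range(20):
            x = np.zeros(18_000)
            _, n, _ = _inject_artifacts(x, 20.0, spec, np.random.default_rng(s))
            counts.append(n)
        assert 24 <= np.mean(counts) <= 36  # E = 30 spikes / 15 min at 2/min


class TestSimulateSubject:
    def test_group_scale_doubles_ground_truth_cs(self):
        base = CouplingSpec(("cardiac", "slow"), {(1, 0, "sin"): 0.1})
        _, m_nc = simulate_subject(DEFAULT_PROFILES["NC"], base, seed=1,
                                   duration=60)
        _, m_ci = simulate_subject(DEFAULT_PROFILES["CI"], base, seed=1,
                                   duration=60)
        assert m_ci["true_cs_vlf_l"] == pytest.approx(2.0 * m_nc["true_cs_vlf_l"])

    def test_ground_truth_cs_monotone_in_coefficient(self):
        strengths = [
            CouplingSpec(("cardiac", "slow"), {(1, 0, "sin"): eps}).strength
            for eps in (0.05, 0.1, 0.2, 0.4)
        ]
        assert strengths == sorted(strengths)
        assert len(set(strengths)) == len(strengths)

    def test_moca_clipped_integer(self):
        for s in range(5):
            _, meta = simulate_subject(DEFAULT_PROFILES["CI"], seed=s,
                                       duration=60)
            assert isinstance(meta["moca"], int)
            assert 0 <= meta["moca"] <= 30

    def test_moca_mean_approaches_profile_mean(self):
        # law of large numbers over the cohort's per-subject draws
        cohort = simulate_cohort({"NC": 60}, seed=2, duration=60)
        assert abs(cohort.metadata["moca"].mean() - 26.94) < 0.5


class TestSimulateCohort:
    def test_banding_rule(self):
        assert moca_band(26) == "NC"
        assert moca_band(25) == "MCI"
        assert moca_band(15) == "MCI"
        assert moca_band(14) == "CI"

    def test_file_layout(self, tmp_path):
        cohort = simulate_cohort({"NC": 1, "MCI": 1, "CI": 1}, seed=1,
                                 duration=60, out_dir=tmp_path)
        assert len(cohort.recordings) == 3
        assert len(list(tmp_path.glob("*_nirs.csv"))) == 3
        assert len(list(tmp_path.glob("*_abp.csv"))) == 3
        assert (tmp_path / "metadata.csv").exists()
        meta = cohort.metadata
        assert {"subject_id", "group", "moca", "true_cs_vlf_l",
                "band_crossed"} <= set(meta.columns)

    def test_same_seed_identical_metadata(self):
        c1 = simulate_cohort({"NC": 2, "CI": 1}, seed=9, duration=60)
        c2 = simulate_cohort({"NC": 2, "CI": 1}, seed=9, duration=60)
        assert c1.metadata.to_csv(index=False) == c2.metadata.to_csv(index=False)
        for r1, r2 in zip(c1.recordings, c2.recordings):
            np.testing.assert_array_equal(r1.channels["ABP"].values,
                                          r2.channels["ABP"].values)

    def test_unknown_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_cohort({"XX": 1}, seed=0, duration=60)

    def test_group_assignment_follows_drawn_score(self):
        cohort = simulate_cohort({"NC": 10, "CI": 10}, seed=4, duration=60)
        for _, row in cohort.metadata.iterrows():
            assert row["group"] == moca_band(row["moca"])
            assert row["band_crossed"] == (row["group"] != row["intended_group"])


class TestSpecValidation:
    def test_oscillator_invariants(self):
        with pytest.raises(InvalidArgumentError):
            OscillatorSpec(-1.0, 0.0)
        with pytest.raises(InvalidArgumentError):
            OscillatorSpec(1.0, -0.1)

    def test_coupling_term_invariants(self):
        with pytest.raises(InvalidArgumentError):
            CouplingSpec(("a", "b"), {(0, 0, "sin"): 0.1})
        with pytest.raises(InvalidArgumentError):
            CouplingSpec(("a", "b"), {(6, 0, "sin"): 0.1})

    def test_group_profile_invariants(self):
        with pytest.raises(InvalidArgumentError):
            GroupProfile("NC", 1, 1, toi_mean=120, toi_sd=4,
                         moca_mean=27, moca_sd=1)
        with pytest.raises(InvalidArgumentError):
            GroupProfile("ZZ", 1, 1, toi_mean=65, toi_sd=4,
                         moca_mean=27, moca_sd=1)
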