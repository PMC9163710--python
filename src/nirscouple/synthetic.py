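"""Synthetic cohorts of coupled-oscillator fNIRS/ABP recordings.

The generator emulates the statistical structure the analysis assumes:
a ~1.1 Hz cardiac oscillation carried by arterial blood pressure, slow
very-low-frequency (0.04 Hz) and low-frequency (0.1 Hz) hemodynamic
oscillations in the hemoglobin channels, and a tunable unidirectional
phase coupling from the cardiac pressure phase into the slow oxyhemoglobin
phases:

    dphi_slow/dt = 2*pi*w + sum_k c_k * trig(a_k*phi_card + b_k*phi_slow)
                   + noise.

A second, group-scaled pathway entrains the slow cerebral oscillators to
slow (0.055 / 0.11 Hz) arterial-pressure oscillations, emulating the
pressure passivity of impaired autoregulation.

Phases are integrated by the Euler-Maruyama scheme, waveforms are
baseline + amplitude*cos(phase) with measurement noise, single-sample
spikes and step-plus-exponential-decay motion transients. Deoxyhemoglobin
is constructed so the clean-signal tissue-oxygenation index matches a
per-side draw from the group profile. Ground-truth coupling strengths are
stored with each subject so that parameter recovery can be tested.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidArgumentError
from .phases import PhaseSeries
from .timeseries import Recording, TimeSeries

__all__ = [
    "OscillatorSpec", "CouplingSpec", "GroupProfile", "ArtifactSpec",
    "DEFAULT_PROFILES", "DEFAULT_BASE_COUPLING", "Cohort",
    "simulate_phase_pair", "synthesize_recording",
    "simulate_subject", "simulate_cohort",
]

#: Largest Fourier index a generative coupling term may use.
K_MAX = 5


@dataclass(frozen=True)
class OscillatorSpec:
    """One phase oscillator: natural frequency, phase noise, waveform amplitude."""

    natural_frequency: float        # Hz
    phase_noise_intensity: float    # rad^2/s
    amplitude: float = 1.0          # signal units
    amplitude_jitter_sd: float = 0.0  # fractional slow amplitude modulation

    def __post_init__(self) -> None:
        if not self.natural_frequency > 0:
            raise InvalidArgumentError("natural_frequency must be > 0")
        if self.phase_noise_intensity < 0 or self.amplitude < 0:
            raise InvalidArgumentError("noise intensity and amplitude must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Directed coupling: trig-basis coefficients from a source to a target phase.

    ``coefficients`` maps (a, b, trig) -> value in rad/s, where the basis
    function is trig(a*phi_source + b*phi_target), trig in {"sin", "cos"}.
    """

    direction: tuple[str, str]
    coefficients: dict[tuple[int, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b, trig) in self.coefficients:
            if (a, b) == (0, 0):
                raise InvalidArgumentError("(a, b) = (0, 0) is not a coupling term")
            if abs(a) > K_MAX or abs(b) > K_MAX:
                raise InvalidArgumentError(f"|a|, |b| must be <= {K_MAX}")
            if trig not in ("sin", "cos"):
                raise InvalidArgumentError("trig must be 'sin' or 'cos'")

    def evaluate(self, phi_source: float | np.ndarray,
                 phi_target: float | np.ndarray) -> float | np.ndarray:
        q = 0.0
        for (a, b, trig), c in self.coefficients.items():
            arg = a * phi_source + b * phi_target
            q = q + c * (np.sin(arg) if trig == "sin" else np.cos(arg))
        return q

    def scaled(self, factor: float) -> "CouplingSpec":
        return CouplingSpec(self.direction,
                            {k: factor * v for k, v in self.coefficients.items()})

    @property
    def strength(self) -> float:
        """Generative coupling strength: Euclidean norm of the coefficients."""
        return float(np.sqrt(sum(v * v for v in self.coefficients.values())))


@dataclass(frozen=True)
class GroupProfile:
    """Group-level effect sizes for the generator."""

    group_name: str                 # NC | MCI | CI
    coupling_scale_vlf: float
    coupling_scale_lf: float
    toi_mean: float                 # %
    toi_sd: float                   # %
    moca_mean: float                # points
    moca_sd: float                  # points

    def __post_init__(self) -> None:
        if self.group_name not in ("NC", "MCI", "CI"):
            raise InvalidArgumentError("group_name must be NC, MCI or CI")
        if not 0 <= self.toi_mean <= 100 or not 0 <= self.moca_mean <= 30:
            raise InvalidArgumentError("toi_mean in [0,100], moca_mean in [0,30]")
        if self.coupling_scale_vlf < 0 or self.coupling_scale_lf < 0:
            raise InvalidArgumentError("coupling scales must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Measurement-artifact rates and magnitudes for the NIRS channels."""

    spike_rate: float = 1.0         # events/min
    spike_amplitude_sd: float = 3.0  # signal units
    motion_rate: float = 0.3        # events/min
    motion_step_sd: float = 2.0     # signal units

    def __post_init__(self) -> None:
        if min(self.spike_rate, self.spike_amplitude_sd,
               self.motion_rate, self.motion_step_sd) < 0:
            raise InvalidArgumentError("artifact rates and amplitudes must be >= 0")


# MoCA means/sds follow the cohort the analysis targets; TOI and coupling
# effect sizes are generator conditions (higher coupling, lower TOI with
# increasing impairment).
DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "NC": GroupProfile("NC", 1.0, 1.0, toi_mean=65.0, toi_sd=4.0,
                       moca_mean=26.94, moca_sd=1.54),
    "MCI": GroupProfile("MCI", 1.5, 1.5, toi_mean=62.0, toi_sd=4.0,
                        moca_mean=20.60, moca_sd=3.42),
    "CI": GroupProfile("CI", 2.0, 2.0, toi_mean=58.0, toi_sd=4.0,
                       moca_mean=10.62, moca_sd=3.16),
}

#: Base cardiac -> slow-oxyhemoglobin coupling before group scaling.
DEFAULT_BASE_COUPLING = CouplingSpec(("cardiac", "slow"),
                                     {(1, 0, "sin"): 0.1})

# Default oscillator parameterisations (band-center frequencies).
DEFAULT_CARDIAC = OscillatorSpec(1.1, 0.05, amplitude=20.0,
                                 amplitude_jitter_sd=0.05)
DEFAULT_VLF = OscillatorSpec(0.04, 0.02, amplitude=1.0,
                             amplitude_jitter_sd=0.1)
DEFAULT_LF = OscillatorSpec(0.1, 0.02, amplitude=0.8,
                            amplitude_jitter_sd=0.1)
# Slow arterial-pressure oscillations, detuned from the cerebral
# oscillators so the entrainment stays below the locking threshold and
# manifests as an in-band beat-frequency modulation of the slow phases.
DEFAULT_ABP_VLF = OscillatorSpec(0.055, 0.005, amplitude=2.0)
DEFAULT_ABP_LF = OscillatorSpec(0.11, 0.005, amplitude=2.0)

#: Pressure-passivity entrainment of the slow cerebral oscillators by the
#: slow ABP oscillations (Adler form sin(phi_abp - phi_o2hb)), in rad/s
#: before group scaling: with impaired autoregulation, more of the slow
#: pressure waves pass into the cerebral slow oscillations.
DEFAULT_ENTRAINMENT = 0.02

ABP_BASELINE = 90.0     # mmHg
O2HB_BASELINE = 30.0    # umol/L (absolute-equivalent)
ABP_NOISE_SD = 1.0      # mmHg
NIRS_NOISE_SD = 0.1     # umol/L
MOTION_TAU = 5.0        # s, decay constant of motion transients


def _integrate(freqs: np.ndarray, noise_intensity: np.ndarray,
               couplings: list[tuple[int, int, CouplingSpec]],
               n_steps: int, step: float, rng: np.random.Generator,
               phi0: np.ndarray | None = None) -> np.ndarray:
    """Euler-Maruyama integration of M coupled phase oscillators.

    ``couplings`` lists (source_index, target_index, spec). Returns
    unwrapped phases of shape (M, n_steps + 1).
    """
    M = freqs.size
    phi = np.zeros((M, n_steps + 1))
    if phi0 is not None:
        phi[:, 0] = phi0
    drift = 2.0 * np.pi * freqs * step
    noise = rng.standard_normal((M, n_steps)) * np.sqrt(noise_intensity * step)[:, None]
    for i in range(n_steps):
        p = phi[:, i]
        dq = np.zeros(M)
        for src, tgt, spec in couplings:
            dq[tgt] += spec.evaluate(p[src], p[tgt])
        phi[:, i + 1] = p + drift + dq * step + noise[:, i]
    return phi


def simulate_phase_pair(
    spec_a: OscillatorSpec,
    spec_b: OscillatorSpec,
    coupling: CouplingSpec | None,
    duration: float,
    step: float,
    seed: int,
    phi0: tuple[float, float] = (0.0, 0.0),
) -> tuple[PhaseSeries, PhaseSeries]:
    """Integrate two stochastic phase oscillators, oscillator a driving b.

    ``coupling.direction`` must reference the oscillators as "a" and "b";
    pass ``None`` for uncoupled oscillators. Phases are returned unwrapped.
    Identical seeds give identical output.
    """
    if duration <= 0 or step <= 0:
        raise InvalidArgumentError("duration and step must be > 0")
    n_steps = int(round(duration / step))
    if n_steps < 1000:
        raise InvalidArgumentError("need >= 1000 samples (duration/step)")
    fmax = max(spec_a.natural_frequency, spec_b.natural_frequency)
    if step * fmax >= 0.1:
        raise InvalidArgumentError(
            f"step {step} too coarse for {fmax} Hz (step*f must be < 0.1)"
        )
    couplings = []
    if coupling is not None and coupling.coefficients:
        names = {"a": 0, "b": 1}
        src, tgt = coupling.direction
        if src not in names or tgt not in names:
            raise InvalidArgumentError(
                f"coupling references unknown oscillator in {coupling.direction}"
            )
        couplings.append((names[src], names[tgt], coupling))
    rng = np.random.default_rng(seed)
    phi = _integrate(
        np.array([spec_a.natural_frequency, spec_b.natural_frequency]),
        np.array([spec_a.phase_noise_intensity, spec_b.phase_noise_intensity]),
        couplings, n_steps, step, rng, phi0=np.asarray(phi0, dtype=float),
    )
    rate = 1.0 / step
    return (PhaseSeries(phi[0], rate), PhaseSeries(phi[1], rate))


def _amplitude_track(base: float, jitter_sd: float, n: int, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Slowly varying amplitude: base * (1 + jitter), jitter low-passed noise."""
    if jitter_sd == 0:
        return np.full(n, base)
    raw = rng.standard_normal(n)
    smooth = gaussian_filter1d(raw, sigma=10.0 * rate)  # ~10 s correlation
    sd = smooth.std() or 1.0
    return base * (1.0 + jitter_sd * smooth / sd)


def _inject_artifacts(x: np.ndarray, rate_hz: float, artifacts: ArtifactSpec,
                      rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Add spikes and motion transients in place; returns (x, n_spikes, n_motion)."""
    n = x.size
    duration_min = n / rate_hz / 60.0
    n_spk = rng.poisson(artifacts.spike_rate * duration_min)
    if n_spk and artifacts.spike_amplitude_sd > 0:
        idx = rng.integers(0, n, n_spk)
        x[idx] += rng.normal(0.0, artifacts.spike_amplitude_sd, n_spk)
    n_mot = rng.poisson(artifacts.motion_rate * duration_min)
    if n_mot and artifacts.motion_step_sd > 0:
        t = np.arange(n) / rate_hz
        for i0 in rng.integers(0, n, n_mot):
            h = rng.normal(0.0, artifacts.motion_step_sd)
            x[i0:] += h * np.exp(-(t[i0:] - t[i0]) / MOTION_TAU)
    return x, int(n_spk), int(n_mot)


def synthesize_recording(
    phases: dict[str, tuple[PhaseSeries, OscillatorSpec]],
    group: GroupProfile,
    artifacts: ArtifactSpec,
    seed: int,
    subject_id: str = "S000",
    abp_rate: float = 1000.0,
    nirs_noise_sd: float = NIRS_NOISE_SD,
    abp_noise_sd: float = ABP_NOISE_SD,
) -> tuple[Recording, dict]:
    """Build the five-channel measurement model from integrated phases.

    ``phases`` must provide "cardiac" plus "VLF_L", "LF_L", "VLF_R",
    "LF_R", each a (PhaseSeries, OscillatorSpec) pair at the NIRS rate.
    Returns the Recording and a dict of drawn values (per-side TOI,
    artifact counts).
    """
    required = {"cardiac", "VLF_L", "LF_L", "VLF_R", "LF_R"}
    missing = required - set(phases)
    if missing:
        raise InvalidArgumentError(f"missing phase components: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    card_ps, card_spec = phases["cardiac"]
    nirs_rate = card_ps.sampling_rate
    n_nirs = card_ps.phase.size
    duration = n_nirs / nirs_rate
    t_nirs = card_ps.times

    # --- ABP at 1000 Hz: baseline + cardiac + small slow waves + noise
    n_abp = int(round(duration * abp_rate))
    t_abp = np.arange(n_abp) / abp_rate
    phi_card_hi = np.interp(t_abp, t_nirs, card_ps.phase)
    amp_card = np.interp(
        t_abp, t_nirs,
        _amplitude_track(card_spec.amplitude, card_spec.amplitude_jitter_sd,
                         n_nirs, nirs_rate, rng),
    )
    abp = ABP_BASELINE + amp_card * np.cos(phi_card_hi)
    for key in ("ABP_VLF", "ABP_LF"):
        if key in phases:
            ps, spec = phases[key]
            abp += spec.amplitude * np.cos(np.interp(t_abp, t_nirs, ps.phase))
        else:
            f_slow = 0.04 if key == "ABP_VLF" else 0.1
            abp += 2.0 * np.cos(2 * np.pi * f_slow * t_abp
                                + rng.uniform(0, 2 * np.pi))
    if abp_noise_sd > 0:
        abp += rng.normal(0.0, abp_noise_sd, n_abp)

    channels = {"ABP": TimeSeries(abp, abp_rate, "ABP", "mmHg")}
    drawn = {}
    counts = {}
    for side in ("L", "R"):
        o2hb = np.full(n_nirs, O2HB_BASELINE)
        for comp in (f"VLF_{side}", f"LF_{side}"):
            ps, spec = phases[comp]
            amp = _amplitude_track(spec.amplitude, spec.amplitude_jitter_sd,
                                   n_nirs, nirs_rate, rng)
            o2hb = o2hb + amp * np.cos(ps.phase)
        clean_mean = o2hb.mean()

        toi = float(rng.normal(group.toi_mean, group.toi_sd))
        toi = float(np.clip(toi, 5.0, 95.0))
        drawn[f"toi_{side}"] = toi
        # HHb baseline forces clean-signal mean TOI == drawn value exactly
        hhb_base = clean_mean * (100.0 - toi) / toi
        fluct = gaussian_filter1d(rng.standard_normal(n_nirs),
                                  sigma=2.0 * nirs_rate)
        if fluct.std() > 0:
            fluct = 0.3 * (fluct - fluct.mean()) / fluct.std()
        hhb = hhb_base + fluct

        if nirs_noise_sd > 0:
            o2hb = o2hb + rng.normal(0.0, nirs_noise_sd, n_nirs)
            hhb = hhb + rng.normal(0.0, nirs_noise_sd, n_nirs)
        o2hb, s1, m1 = _inject_artifacts(o2hb, nirs_rate, artifacts, rng)
        hhb, s2, m2 = _inject_artifacts(hhb, nirs_rate, artifacts, rng)
        counts[side] = {"n_spikes": s1 + s2, "n_motion": m1 + m2}

        channels[f"O2Hb_{side}"] = TimeSeries(o2hb, nirs_rate,
                                              f"O2Hb_{side}", "umol/L")
        channels[f"HHb_{side}"] = TimeSeries(hhb, nirs_rate,
                                             f"HHb_{side}", "umol/L")

    rec = Recording(channels, subject_id=subject_id)
    rec.log("synthesize_recording", seed=seed, group=group.group_name,
            artifact_counts=counts)
    drawn["artifact_counts"] = counts
    return rec, drawn


def simulate_subject(
    group: GroupProfile,
    base_coupling: CouplingSpec = DEFAULT_BASE_COUPLING,
    seed: int | np.random.SeedSequence = 0,
    duration: float = 900.0,
    nirs_rate: float = 20.0,
    artifacts: ArtifactSpec = ArtifactSpec(),
    subject_id: str = "S000",
    cardiac: OscillatorSpec = DEFAULT_CARDIAC,
    vlf: OscillatorSpec = DEFAULT_VLF,
    lf: OscillatorSpec = DEFAULT_LF,
    abp_vlf: OscillatorSpec = DEFAULT_ABP_VLF,
    abp_lf: OscillatorSpec = DEFAULT_ABP_LF,
    entrainment: float = DEFAULT_ENTRAINMENT,
) -> tuple[Recording, dict]:
    """One synthetic subject: coupled phases, waveforms, metadata.

    Two coupling pathways act on the slow cerebral oscillators, both
    scaled by the group's per-band coupling scale: the cardiac
    cross-frequency coupling (``base_coupling``, whose scaled generative
    strength is stored under ``true_cs_*`` for recovery tests) and the
    pressure-passivity entrainment by the slow ABP oscillations. The MoCA
    score is drawn from the group profile, clipped to [0, 30] and rounded.
    """
    for s in (group.coupling_scale_vlf, group.coupling_scale_lf):
        if not np.isfinite(s):
            raise InvalidArgumentError("group coupling scales must be finite")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seeds = ss.generate_state(3)
    rng = np.random.default_rng(seeds[0])

    cpl_vlf = base_coupling.scaled(group.coupling_scale_vlf)
    cpl_lf = base_coupling.scaled(group.coupling_scale_lf)
    ent_vlf = CouplingSpec(("abp_slow", "slow"), {(1, -1, "sin"): entrainment}
                           ).scaled(group.coupling_scale_vlf)
    ent_lf = CouplingSpec(("abp_slow", "slow"), {(1, -1, "sin"): entrainment}
                          ).scaled(group.coupling_scale_lf)

    step = 1.0 / nirs_rate
    n_steps = int(round(duration / step))
    # joint integration, index order:
    # 0 cardiac, 1 ABP-VLF, 2 ABP-LF, 3 VLF_L, 4 LF_L, 5 VLF_R, 6 LF_R
    freqs = np.array([cardiac.natural_frequency,
                      abp_vlf.natural_frequency, abp_lf.natural_frequency] +
                     [vlf.natural_frequency, lf.natural_frequency] * 2)
    noise_int = np.array([cardiac.phase_noise_intensity,
                          abp_vlf.phase_noise_intensity,
                          abp_lf.phase_noise_intensity] +
                         [vlf.phase_noise_intensity,
                          lf.phase_noise_intensity] * 2)
    couplings = [(0, 3, cpl_vlf), (0, 4, cpl_lf),
                 (0, 5, cpl_vlf), (0, 6, cpl_lf),
                 (1, 3, ent_vlf), (2, 4, ent_lf),
                 (1, 5, ent_vlf), (2, 6, ent_lf)]
    phi0 = rng.uniform(0.0, 2.0 * np.pi, 7)
    phi = _integrate(freqs, noise_int, couplings, n_steps, step,
                     np.random.default_rng(seeds[1]), phi0=phi0)
    ps = [PhaseSeries(row, nirs_rate) for row in phi]
    phase_map = {
        "cardiac": (ps[0], cardiac),
        "ABP_VLF": (ps[1], abp_vlf), "ABP_LF": (ps[2], abp_lf),
        "VLF_L": (ps[3], vlf), "LF_L": (ps[4], lf),
        "VLF_R": (ps[5], vlf), "LF_R": (ps[6], lf),
    }
    rec, drawn = synthesize_recording(phase_map, group, artifacts,
                                      seed=int(seeds[2]),
                                      subject_id=subject_id)

    moca = int(round(float(np.clip(rng.normal(group.moca_mean, group.moca_sd),
                                   0.0, 30.0))))
    meta = {
        "subject_id": subject_id,
        "intended_group": group.group_name,
        "moca": moca,
        "true_cs_vlf_l": cpl_vlf.strength,
        "true_cs_lf_l": cpl_lf.strength,
        "true_cs_vlf_r": cpl_vlf.strength,
        "true_cs_lf_r": cpl_lf.strength,
        "drawn_toi_l": drawn["toi_L"],
        "drawn_toi_r": drawn["toi_R"],
    }
    return rec, meta


def moca_band(score: int) -> str:
    """Group assignment from a MoCA score: >=26 NC, 15-25 MCI, <=14 CI."""
    if score >= 26:
        return "NC"
    if score >= 15:
        return "MCI"
    return "CI"


@dataclass
class Cohort:
    """In-memory synthetic cohort: recordings plus a metadata table."""

    recordings: list[Recording]
    metadata: pd.DataFrame


def simulate_cohort(
    n_per_group: dict[str, int],
    profiles: dict[str, GroupProfile] | None = None,
    seed: int = 0,
    base_coupling: CouplingSpec = DEFAULT_BASE_COUPLING,
    duration: float = 900.0,
    artifacts: ArtifactSpec = ArtifactSpec(),
    out_dir=None,
) -> Cohort:
    """Generate a cohort; optionally write it to ``out_dir``.

    Each subject's random stream derives from (cohort seed, subject index)
    through a counter-based seed sequence, so generation is reproducible
    independent of order. Final group labels follow the MoCA banding rule
    applied to each drawn score; ``band_crossed`` flags subjects whose
    drawn score left the intended band.
    """
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    rows = []
    recs = []
    idx = 0
    for gname in sorted(n_per_group):
        if gname not in profiles:
            raise InvalidArgumentError(f"unknown group {gname!r}")
        n = n_per_group[gname]
        if n < 1:
            raise InvalidArgumentError("n_per_group counts must be >= 1")
        for _ in range(n):
            sid = f"S{idx:03d}"
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            rec, meta = simulate_subject(
                profiles[gname], base_coupling, seed=ss, duration=duration,
                artifacts=artifacts, subject_id=sid,
            )
            assigned = moca_band(meta["moca"])
            meta["group"] = assigned
            meta["band_crossed"] = assigned != meta["intended_group"]
            rows.append(meta)
            recs.append(rec)
            idx += 1
    metadata = pd.DataFrame(rows)
    cohort = Cohort(recs, metadata)
    if out_dir is not None:
        from .io import write_cohort
        write_cohort(cohort, out_dir)
    return cohort
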