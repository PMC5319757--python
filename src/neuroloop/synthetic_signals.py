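"""Seeded generators of synthetic test inputs.

Provides the study conditions for the rest of the package: Hindmarsh-Rose
bursting membrane traces, spike trains with prescribed interspike-interval
structure, LFP surrogates with controllable beta-phase to high-frequency-
amplitude coupling at a given SNR, ground-truth phase-model parameter sets
for three site archetypes, and paired (LFP, spike train) recordings built
from a known parameter set for estimator-recovery checks.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import zlib

import numpy as np

from neuroloop.phase_model import PhaseModelParams
from neuroloop.signals import SampledSignal

__all__ = [
    "HRParams",
    "CoupledLFPSpec",
    "SpikeTrainSpec",
    "generate_hindmarsh_rose",
    "synthesize_coupled_lfp",
    "generate_spike_train",
    "generate_model_params",
    "synthesize_paired_recording",
    "ARCHETYPES",
]

from dataclasses import dataclass


@dataclass
class HRParams:
    """Hindmarsh-Rose model coefficients (dimensionless).

    Defaults put the model in the canonical square-wave bursting regime
    (a=1, b=3, c=1, d=5, s=4, x_rest=-1.6, r_slow=0.001, I_app=2).
    ``time_scale`` maps one dimensionless model time unit to wall-clock time
    (units 1/s); the default 800 makes one unit 1.25 ms, so intraburst
    interspike intervals land near 0.02 s, as in pathological subthalamic
    bursting.  ``dt`` is the integration step in seconds.
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    d: float = 5.0
    s: float = 4.0
    x_rest: float = -1.6
    r_slow: float = 0.001
    I_app: float = 2.0
    time_scale: float = 800.0
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("integration step dt must be positive")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")
        for name in ("a", "b", "c", "d", "s", "x_rest", "r_slow", "I_app"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")


@dataclass
class CoupledLFPSpec:
    """LFP surrogate: beta rhythm + HFO carrier with phase-locked amplitude.

    The high-frequency carrier amplitude is modulated by the beta phase,
    A(t) = 1 + coupling_strength * cos(phi_beta(t)); Gaussian measurement
    noise is added at ``snr_db`` relative to the clean composite signal.
    """

    beta_freq: float = 20.0
    hfo_freq: float = 250.0
    coupling_strength: float = 0.9
    snr_db: float = 20.0
    fs: float = 2000.0
    duration: float = 10.0
    seed: int = 0
    beta_amp: float = 1.0
    hfo_amp: float = 0.5
    #: spectral width (Lorentzian FWHM, Hz) of the high-frequency carrier's
    #: phase diffusion; real high-frequency band activity has finite
    #: coherence, not an infinitely coherent tone
    carrier_bw: float = 10.0

    def __post_init__(self) -> None:
        if not 13.0 <= self.beta_freq <= 30.0:
            raise ValueError("beta_freq must lie in [13, 30] Hz")
        if not 200.0 <= self.hfo_freq <= 500.0:
            raise ValueError("hfo_freq must lie in [200, 500] Hz")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.fs <= 2 * self.hfo_freq:
            raise ValueError(
                f"fs={self.fs} Hz aliases the {self.hfo_freq} Hz carrier "
                "(need fs > 2*hfo_freq)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SpikeTrainSpec:
    """Spike-train generator specification.

    ``pattern`` is one of ``regular`` (equispaced at ``rate``), ``poisson``
    (exponential ISIs at ``rate``) or ``bursting`` (exponential interburst
    intervals, Poisson burst sizes, short exponential intraburst ISIs; the
    ``rate`` field is ignored for bursting).
    """

    pattern: str = "poisson"
    rate: float = 20.0
    intraburst_isi_mean: float = 0.02
    interburst_interval_mean: float = 0.25
    spikes_per_burst_mean: float = 5.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("regular", "poisson", "bursting"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.pattern == "bursting" and not (
            self.intraburst_isi_mean < self.interburst_interval_mean
        ):
            raise ValueError(
                "bursting requires intraburst_isi_mean < interburst_interval_mean"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def generate_hindmarsh_rose(params: HRParams, duration: float) -> SampledSignal:
    """Fixed-step RK4 integration of the Hindmarsh-Rose membrane equations.

        x' = y + b x^2 - a x^3 - z + I_app
        y' = c - d x^2 - y
        z' = r_slow (s (x - x_rest) - z)

    Returns the membrane variable x sampled at 1/dt; spike times can be
    recovered by threshold crossing (:func:`neuroloop.biomarker.detect_spikes`).
    The integration is deterministic (no noise term).
    """
    if duration < 10 * params.dt:
        raise ValueError("duration must cover at least 10 integration steps")
    a, b, c, d = params.a, params.b, params.c, params.d
    s, x_rest, r_slow, I = params.s, params.x_rest, params.r_slow, params.I_app
    scale = params.time_scale
    dt = params.dt
    n = int(round(duration / dt))

    def deriv(x, y, z):
        return (
            scale * (y + b * x * x - a * x**3 - z + I),
            scale * (c - d * x * x - y),
            scale * (r_slow * (s * (x - x_rest) - z)),
        )

    x, y, z = x_rest, c - d * x_rest**2, 0.0
    out = np.empty(n)
    for k in range(n):
        k1 = deriv(x, y, z)
        k2 = deriv(x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1], z + 0.5 * dt * k1[2])
        k3 = deriv(x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1], z + 0.5 * dt * k2[2])
        k4 = deriv(x + dt * k3[0], y + dt * k3[1], z + dt * k3[2])
        x += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        z += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            raise FloatingPointError(
                f"non-finite Hindmarsh-Rose state at step {k} (t={k * dt:.6g})"
            )
        out[k] = x
    return SampledSignal(samples=out, fs=1.0 / dt, channel_meta={"model": "hindmarsh-rose"})


def synthesize_coupled_lfp(spec: CoupledLFPSpec) -> SampledSignal:
    """Surrogate LFP with beta-phase to HFO-amplitude coupling at given SNR.

    The high-frequency carrier is a constant-modulus oscillation at
    ``hfo_freq`` with Wiener phase diffusion giving it a Lorentzian linewidth
    of ``carrier_bw`` Hz (finite coherence, as in real high-frequency band
    activity); its amplitude is modulated by the beta phase with depth
    ``coupling_strength``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(round(spec.duration * spec.fs))) / spec.fs
    dt = 1.0 / spec.fs
    beta_phase = 2 * np.pi * spec.beta_freq * t
    beta = spec.beta_amp * np.sin(beta_phase)
    amp = 1.0 + spec.coupling_strength * np.cos(beta_phase)
    # Wiener phase with diffusion D = 2*pi*FWHM (rad^2/s)
    d_theta = np.sqrt(2 * np.pi * spec.carrier_bw * dt) * rng.standard_normal(t.size)
    theta = np.cumsum(d_theta)
    carrier = np.sin(2 * np.pi * spec.hfo_freq * t + theta)
    hfo = spec.hfo_amp * amp * carrier
    clean = beta + hfo
    noise_power = np.mean(clean**2) / 10 ** (spec.snr_db / 10.0)
    noise = np.sqrt(noise_power) * rng.standard_normal(t.size)
    return SampledSignal(
        samples=clean + noise,
        fs=spec.fs,
        channel_meta={
            "kind": "coupled-lfp-surrogate",
            "coupling": f"{spec.coupling_strength:g}",
            "snr_db": f"{spec.snr_db:g}",
        },
    )


def generate_spike_train(spec: SpikeTrainSpec) -> np.ndarray:
    """Sorted, strictly increasing spike times in [0, duration]."""
    rng = np.random.default_rng(spec.seed)
    if spec.pattern == "regular":
        expected = spec.rate * spec.duration
        if expected < 2:
            raise ValueError("spec yields fewer than 2 expected spikes")
        times = np.arange(1, int(np.floor(expected)) + 1) / spec.rate
    elif spec.pattern == "poisson":
        expected = spec.rate * spec.duration
        if expected < 2:
            raise ValueError("spec yields fewer than 2 expected spikes")
        n_draw = int(expected + 6 * np.sqrt(expected) + 10)
        isis = rng.exponential(1.0 / spec.rate, size=n_draw)
        times = np.cumsum(isis)
        times = times[times <= spec.duration]
    else:  # bursting
        expected_bursts = spec.duration / spec.interburst_interval_mean
        if expected_bursts * spec.spikes_per_burst_mean < 2:
            raise ValueError("spec yields fewer than 2 expected spikes")
        times_list = []
        t = rng.exponential(spec.interburst_interval_mean)
        while t <= spec.duration:
            n_spk = 1 + rng.poisson(max(spec.spikes_per_burst_mean - 1, 0.0))
            isis = rng.exponential(spec.intraburst_isi_mean, size=n_spk - 1)
            burst = t + np.concatenate([[0.0], np.cumsum(isis)])
            times_list.append(burst[burst <= spec.duration])
            t += rng.exponential(spec.interburst_interval_mean)
        times = np.concatenate(times_list) if times_list else np.array([])
    times = np.sort(times)
    # enforce strict monotonicity (overlapping bursts can collide)
    if times.size > 1:
        times = np.maximum.accumulate(times + np.arange(times.size) * 1e-9)
    if times.size < 2:
        raise ValueError("generated fewer than 2 spikes; spec infeasible")
    return times


#: archetype parameter ranges: (omega range (bursts/s), sigma_I range,
#: sigma_C range, r range, K range).  ocd_high_rate mirrors the high-
#: discharge-rate group (mean ISI ~0.029 s, strongly dispersed ISIs),
#: ocd_low_rate the low-rate group (mean ISI ~0.107 s, tighter relative
#: dispersion), pd_bursting the PD bursting group (mean ISI ~0.024 s).
ARCHETYPES = {
    "pd_bursting": {
        "omega": (6.0, 8.0), "sigma_I": (0.30, 0.45), "sigma_C": (0.05, 0.10),
        "r": (0.4, 0.7), "K": (0.2, 0.4), "mu_isi": 0.0242,
    },
    "ocd_high_rate": {
        "omega": (7.0, 9.0), "sigma_I": (0.40, 0.55), "sigma_C": (0.05, 0.10),
        "r": (0.4, 0.6), "K": (0.2, 0.4), "mu_isi": 0.0289,
    },
    "ocd_low_rate": {
        "omega": (2.0, 4.0), "sigma_I": (0.20, 0.30), "sigma_C": (0.05, 0.10),
        "r": (0.5, 0.7), "K": (0.3, 0.5), "mu_isi": 0.1072,
    },
}


def generate_model_params(archetype: str, seed: int = 0) -> PhaseModelParams:
    """Ground-truth phase-model parameter set for a site archetype.

    Archetypes differ in natural (burst-cycle) frequency and noise levels:
    ``ocd_high_rate`` sites fire fast with short, strongly dispersed ISIs,
    ``ocd_low_rate`` sites fire slowly, ``pd_bursting`` sites resemble the
    bursting group seen in Parkinson's disease.  The phase shift a = 1/4 and
    default PRC / sensitivity curves are attached; 0 < r < 1 always (partially
    synchronous quasiperiodic surround).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; choose from {sorted(ARCHETYPES)}"
        )
    spec = ARCHETYPES[archetype]
    tag = zlib.crc32(archetype.encode()) % (2**31)
    rng = np.random.default_rng([seed, tag])
    draw = lambda key: float(rng.uniform(*spec[key]))  # noqa: E731
    return PhaseModelParams(
        omega=draw("omega"),
        K=draw("K"),
        r=draw("r"),
        psi=float(rng.uniform(0.0, 1.0)),
        sigma_I=draw("sigma_I"),
        sigma_C=draw("sigma_C"),
    )


def synthesize_paired_recording(
    params: PhaseModelParams,
    beta_freq: float = 20.0,
    duration: float = 60.0,
    fs: float = 1000.0,
    spikes_per_burst: int = 4,
    intraburst_isi: float = 0.006,
    noise_amp: float = 0.3,
    seed: int = 0,
) -> tuple[SampledSignal, np.ndarray]:
    """Paired (LFP, spike train) recording consistent with a parameter set.

    Burst cycles occur at the model's natural frequency ``omega``; each burst
    onset is locked to the beta-band LFP rhythm at mean phase ``psi`` with
    wrapped-normal jitter whose width is chosen so that the circular resultant
    of onset phases equals ``r``.  Intended for estimator-recovery tests of
    :func:`neuroloop.phase_model.estimate_model_params`.
    """
    rng = np.random.default_rng(seed)
    n_bursts = int(params.omega * duration)
    if n_bursts < 3:
        raise ValueError("duration too short for the requested burst rate")
    # wrapped-normal width giving circular resultant r: r = exp(-sw^2/2)
    sw = np.sqrt(-2.0 * np.log(np.clip(params.r, 1e-6, 1 - 1e-12)))
    nominal = np.arange(1, n_bursts + 1) / params.omega
    onset_angles = 2 * np.pi * params.psi + sw * rng.standard_normal(n_bursts)
    # snap each nominal onset to the nearest beta cycle carrying its angle
    cycle = np.round(beta_freq * nominal - onset_angles / (2 * np.pi))
    onsets = (cycle + onset_angles / (2 * np.pi)) / beta_freq
    onsets = np.sort(onsets[(onsets > 0) & (onsets < duration - 0.1)])

    spikes = []
    for t0 in onsets:
        spikes.extend(t0 + intraburst_isi * np.arange(spikes_per_burst))
    spikes = np.sort(np.asarray(spikes))
    spikes = np.maximum.accumulate(spikes + np.arange(spikes.size) * 1e-9)

    t = np.arange(int(duration * fs)) / fs
    # beta rhythm uses a sine so that hilbert-phase 0 aligns with cos(0)=peak
    lfp = np.cos(2 * np.pi * beta_freq * t) + noise_amp * rng.standard_normal(t.size)
    return (
        SampledSignal(samples=lfp, fs=fs, channel_meta={"kind": "paired-surrogate"}),
        spikes,
    )
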