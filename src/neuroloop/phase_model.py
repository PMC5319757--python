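"""Stochastic phase-reduced bursting-neuron model under impulsive stimulation.

The oscillator phase ``phi`` in [0, 1) obeys the Ito stochastic differential
equation

    dphi = [ omega + K r sin(2 pi (psi - phi + a)) + v_C
             + (sigma_I / 2) R_I'(phi) (sigma_I R_I(phi) + D_C) ] dt
           + (sigma_I R_I(phi) + D_C) dW
           + Delta(phi, beta) sum_k delta(t - tau_k)

where ``omega`` is the natural (burst-cycle) frequency, ``K``, ``r`` and
``psi`` describe the coupling to the surrounding partially synchronous
population, ``a`` is the coupling phase shift (1/4), ``R_I`` and ``R_C`` are
the phase sensitivity functions to independent and common noise, ``v_C`` and
``D_C`` are the effective drift and diffusion contributed by the colored
common noise with autocorrelation ``C(s)``, and ``Delta(phi, beta)`` is the
phase response curve (PRC) to a single stimulation impulse of strength
``beta = w I0 / C`` (pulse width ``w`` in microseconds, current ``I0`` in
amperes, membrane capacitance ``C = 1 uF/cm^2``).  Impulse times ``tau_k``
form a Poisson-parametrized train with mean frequency ``f`` and regularity
dial ``lambda``.

The drift's third term is the standard Ito correction (1/2) g g' for the
state-dependent diffusion g(phi) = sigma_I R_I(phi) + D_C; the literal
sigma_I^2 reading of the printed coefficient is available through the
``ito_literal`` switch of :func:`simulate_phase_sde`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

from neuroloop.biomarker import classify_firing_pattern, compute_isi_stats
from neuroloop.signals import SampledSignal

__all__ = [
    "PhaseModelParams",
    "StimulusSettings",
    "StimulusTrain",
    "PhaseTrajectory",
    "SETTINGS_BOUNDS",
    "default_phase_grid",
    "default_prc",
    "default_sensitivity_curves",
    "estimate_order_parameter",
    "estimate_model_params",
    "colored_noise_coefficients",
    "prc_lookup",
    "sample_stimulus_train",
    "simulate_phase_sde",
    "simulate_phase_ensemble",
    "periodic_interp",
]

#: box constraints of the stimulation decision vector [w (us), I0 (A),
#: f (Hz), lambda]
SETTINGS_BOUNDS = {
    "w": (30.0, 210.0),
    "I0": (0.001, 0.004),
    "f": (20.0, 150.0),
    "lam": (3.0, 30.0),
}

_GRID_SIZE = 128


def default_phase_grid(n: int = _GRID_SIZE) -> np.ndarray:
    return np.arange(n) / n


def default_prc(grid: np.ndarray | None = None, amplitude: float = 0.05) -> np.ndarray:
    """Synthetic biphasic (type-II-like) PRC of a bursting oscillator.

    A stand-in for a PRC derived from the Hindmarsh-Rose phase reduction:
    phase delay when the impulse arrives early in the cycle, advance late in
    the cycle, vanishing at the burst onset.  Tabulated at the reference
    perturbation strength; users supply their own table for a specific cell.
    """
    grid = default_phase_grid() if grid is None else grid
    return amplitude * (-np.sin(2 * np.pi * grid) + 0.4 * np.sin(4 * np.pi * grid))


def default_sensitivity_curves(grid: np.ndarray | None = None):
    """Synthetic phase sensitivity curves (R_I, R_C) on the grid.

    Simple smooth placeholders for curves obtained from a full phase
    reduction: R_I(phi) = 1 + 0.5 sin(2 pi phi), R_C(phi) = sin(2 pi phi).
    """
    grid = default_phase_grid() if grid is None else grid
    return 1.0 + 0.5 * np.sin(2 * np.pi * grid), np.sin(2 * np.pi * grid)


def periodic_interp(table: np.ndarray, phi) -> np.ndarray:
    """Linear interpolation of a 1-periodic table sampled on a uniform grid."""
    table = np.asarray(table, dtype=float)
    n = table.size
    pos = (np.asarray(phi, dtype=float) % 1.0) * n
    i0 = np.floor(pos).astype(int) % n
    frac = pos - np.floor(pos)
    return table[i0] * (1.0 - frac) + table[(i0 + 1) % n] * frac


def _spectral_derivative(table: np.ndarray) -> np.ndarray:
    """d/dphi of a 1-periodic table via its Fourier series."""
    n = table.size
    k = np.fft.fftfreq(n, d=1.0 / n)
    return np.real(np.fft.ifft(np.fft.fft(table) * 2j * np.pi * k))


@dataclass
class PhaseModelParams:
    """All parameters of the stochastic phase equation.

    Curves are tabulated on a common uniform phase grid on [0, 1); the
    derivative tables are computed spectrally from the value tables.  ``v_C``
    and ``D_C`` are filled in by :func:`colored_noise_coefficients` (lazily on
    first access if left as None).
    """

    omega: float
    K: float
    r: float
    psi: float
    sigma_I: float
    sigma_C: float
    a: float = 0.25
    phase_grid: np.ndarray = field(default_factory=default_phase_grid)
    R_I: np.ndarray | None = None
    R_C: np.ndarray | None = None
    prc: np.ndarray | None = None
    #: perturbation strength (beta = w*I0/C) at which the PRC table was
    #: constructed; 0.42 corresponds to a strong 210 us / 2 mA pulse, so the
    #: linear beta/beta_ref scaling interpolates within the operating range
    #: instead of extrapolating far beyond the table
    beta_ref: float = 0.42
    corr_form: str = "exp"
    tau_corr: float = 0.02
    membrane_C: float = 1.0
    v_C: float | None = None
    D_C: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"order parameter r must lie in [0, 1], got {self.r}")
        if self.sigma_I < 0 or self.sigma_C < 0:
            raise ValueError("noise intensities must be non-negative")
        self.phase_grid = np.asarray(self.phase_grid, dtype=float)
        if self.R_I is None or self.R_C is None:
            r_i, r_c = default_sensitivity_curves(self.phase_grid)
            self.R_I = r_i if self.R_I is None else np.asarray(self.R_I, float)
            self.R_C = r_c if self.R_C is None else np.asarray(self.R_C, float)
        else:
            self.R_I = np.asarray(self.R_I, dtype=float)
            self.R_C = np.asarray(self.R_C, dtype=float)
        if self.prc is None:
            self.prc = default_prc(self.phase_grid)
        else:
            self.prc = np.asarray(self.prc, dtype=float)
        if not (
            self.phase_grid.size == self.R_I.size == self.R_C.size == self.prc.size
        ):
            raise ValueError("all curves must share the phase grid")
        self.R_I_prime = _spectral_derivative(self.R_I)
        self.R_C_prime = _spectral_derivative(self.R_C)

    def noise_coefficients(self) -> tuple[float, float]:
        """(v_C, D_C), computing them from the curves if not yet set."""
        if self.v_C is None or self.D_C is None:
            self.v_C, self.D_C = colored_noise_coefficients(
                self.R_C, self.corr_descriptor(), self.omega, self.sigma_C,
                phase_grid=self.phase_grid,
            )
        return self.v_C, self.D_C

    def corr_descriptor(self) -> dict:
        return {"form": self.corr_form, "tau": self.tau_corr}

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        v_c, d_c = self.noise_coefficients()
        return {
            "omega": self.omega, "K": self.K, "r": self.r, "psi": self.psi,
            "a": self.a, "sigma_I": self.sigma_I, "sigma_C": self.sigma_C,
            "phase_grid": self.phase_grid.tolist(),
            "R_I": self.R_I.tolist(), "R_C": self.R_C.tolist(),
            "prc": self.prc.tolist(), "beta_ref": self.beta_ref,
            "corr_form": self.corr_form, "tau_corr": self.tau_corr,
            "membrane_C": self.membrane_C, "v_C": v_c, "D_C": d_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseModelParams":
        d = dict(d)
        for key in ("phase_grid", "R_I", "R_C", "prc"):
            if key in d and d[key] is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class StimulusSettings:
    """Stimulation decision vector x = [w, I0, f, lam].

    ``w`` pulse width (microseconds), ``I0`` current amplitude (A), ``f`` mean
    stimulation frequency (Hz), ``lam`` Poisson regularity parameter (higher
    means more regular inter-impulse intervals; ``inf`` is the deterministic
    "regular" surrogate used to model conventional fixed-rate stimulation).
    """

    w: float
    I0: float
    f: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("w", "I0", "f"):
            lo, hi = SETTINGS_BOUNDS[name]
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")
        lo, hi = SETTINGS_BOUNDS["lam"]
        if not (lo <= self.lam <= hi or np.isinf(self.lam)):
            raise ValueError(
                f"lam={self.lam} outside bounds [{lo}, {hi}] (or inf for the "
                "regular surrogate)"
            )

    @classmethod
    def regular_surrogate(cls, w: float, I0: float, f: float) -> "StimulusSettings":
        """Deterministic fixed-rate stimulation (the lam -> inf extreme)."""
        return cls(w=w, I0=I0, f=f, lam=np.inf)

    def as_vector(self) -> np.ndarray:
        return np.array([self.w, self.I0, self.f, self.lam])


@dataclass
class StimulusTrain:
    """Sorted impulse times with the effective impulse strength beta."""

    tau_k: np.ndarray
    beta: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tau_k = np.asarray(self.tau_k, dtype=float)
        if self.tau_k.size > 1 and np.any(np.diff(self.tau_k) <= 0):
            raise ValueError("impulse times must be strictly increasing")
        if self.beta <= 0:
            raise ValueError("impulse strength beta must be positive")


@dataclass
class PhaseTrajectory:
    """Simulated phase path: wrapped phase, unwrapped phase, impulse markers."""

    t: np.ndarray
    phi: np.ndarray
    phi_unwrapped: np.ndarray
    impulse_index: np.ndarray


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_order_parameter(phases) -> tuple[float, float]:
    """Kuramoto order parameter (r, psi) of phases given in cycles [0, 1).

    (r, psi) is the polar form of the circular mean of the unit phasors;
    r = 1 for perfectly aligned phases, r = 0 for a balanced distribution.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    if phases.size == 0:
        raise ValueError("need at least one phase sample")
    z = np.mean(np.exp(2j * np.pi * phases))
    return float(np.abs(z)), float((np.angle(z) / (2 * np.pi)) % 1.0)


def _burst_onsets(spikes: np.ndarray, gap_factor: float = 2.5) -> np.ndarray:
    """First-spike times of bursts, split at ISI gaps above gap_factor*median."""
    isi = np.diff(spikes)
    threshold = gap_factor * np.median(isi)
    onsets = [spikes[0]]
    onsets.extend(spikes[1:][isi > threshold])
    return np.asarray(onsets)


def estimate_model_params(
    lfp: SampledSignal, spikes, config: dict | None = None
) -> PhaseModelParams:
    """Fit the phase model to a paired (LFP, spike train) recording.

    The recording must exhibit a bursting firing pattern (the model is a
    bursting-oscillator abstraction); otherwise a refusal error names the
    gate.  The estimators are deliberately simple:

    - ``omega``: burst-cycle rate (bursts per second), bursts delimited by
      ISI gaps above ``burst_gap_factor`` times the median ISI;
    - ``(r, psi)``: circular mean of the beta-band LFP phases at burst onsets;
    - ``sigma_I``: from burst-cycle interval dispersion via the phase-diffusion
      relation Var(T) = sigma^2 / omega^3;
    - ``sigma_C``: ``sigma_C_scale`` times the square root of the relative
      beta-band LFP power;
    - ``K``: ``K_scale`` times the estimated r.
    """
    config = dict(config or {})
    spikes = np.sort(np.asarray(spikes, dtype=float).ravel())
    if spikes.size < 10:
        raise ValueError(f"need at least 10 spikes, got {spikes.size}")
    stats_ = compute_isi_stats(spikes)
    pattern = classify_firing_pattern(stats_)
    if pattern != "bursting":
        raise ValueError(
            "firing-pattern gate: recording classified as non-bursting; the "
            "phase model targets bursting sites only"
        )

    onsets = _burst_onsets(spikes, config.get("burst_gap_factor", 2.5))
    span = spikes[-1] - spikes[0]
    omega = max(len(onsets) / span, 1e-6)

    beta_band = tuple(config.get("beta_band", (13.0, 30.0)))
    sos = signal.butter(4, list(beta_band), btype="bandpass", fs=lfp.fs, output="sos")
    analytic = signal.hilbert(signal.sosfiltfilt(sos, lfp.samples))
    lfp_phase = (np.angle(analytic) / (2 * np.pi)) % 1.0
    idx = np.clip((onsets * lfp.fs).astype(int), 0, len(lfp) - 1)
    r, psi = estimate_order_parameter(lfp_phase[idx])

    if len(onsets) >= 3:
        var_cycle = float(np.var(np.diff(onsets)))
    else:
        var_cycle = stats_.var_isi
    sigma_I = float(np.sqrt(max(var_cycle, 1e-12) * omega**3))

    beta_power = float(np.mean(np.abs(analytic) ** 2) / 2.0)
    total_power = float(np.var(lfp.samples))
    sigma_C = float(
        config.get("sigma_C_scale", 0.1) * np.sqrt(beta_power / max(total_power, 1e-30))
    )
    K = float(config.get("K_scale", 1.0)) * r
    return PhaseModelParams(
        omega=omega, K=K, r=r, psi=psi, sigma_I=sigma_I, sigma_C=sigma_C,
    )


# ---------------------------------------------------------------------------
# colored-noise coefficients
# ---------------------------------------------------------------------------

def _corr_function(c_corr):
    """Return (C(s) callable, tau scale) from a descriptor or callable."""
    if callable(c_corr):
        return c_corr, None
    form = c_corr.get("form", "exp")
    tau = float(c_corr.get("tau"))
    if not np.isfinite(tau) or tau <= 0:
        raise ValueError(f"autocorrelation timescale must be finite positive, got {tau}")
    if form == "exp":
        return (lambda s: np.exp(-np.abs(s) / tau)), tau
    raise ValueError(f"unknown autocorrelation form {form!r}")


def colored_noise_coefficients(
    R_C, c_corr, omega: float, sigma_C: float, phase_grid=None,
) -> tuple[float, float]:
    """Effective drift v_C and diffusion D_C of the colored common noise.

        v_C = sigma_C^2 * int_0^inf ds C(s) int_0^1 dphi R_C'(phi) R_C(phi - omega s)
        D_C = sigma_C^2 * int_-inf^inf ds C(s) int_0^1 dphi R_C(phi) R_C(phi - omega s)

    The inner phase integrals are evaluated exactly through the Fourier series
    of the tabulated R_C (band-limited on its grid); the outer time integrals
    use adaptive quadrature against the autocorrelation C(s), which must have
    a finite timescale.
    """
    R_C = np.asarray(R_C, dtype=float)
    n = R_C.size
    coeff = np.fft.rfft(R_C) / n
    k = np.arange(coeff.size)
    # |c_k|^2 weights; double non-edge harmonics to account for +-k pairs
    w_k = np.abs(coeff) ** 2
    w_k[1:] *= 2.0
    if n % 2 == 0 and coeff.size == n // 2 + 1:
        w_k[-1] /= 2.0  # Nyquist term is not paired
    w_k[0] = np.abs(coeff[0]) ** 2  # DC: R_C' kills it in v_C anyway

    corr, tau = _corr_function(c_corr)
    if tau is None:
        # probe the decay to pick an integration horizon
        probe = np.logspace(-4, 2, 61)
        vals = np.abs(corr(probe))
        finite = probe[vals > 1e-12 * max(vals.max(), 1e-300)]
        if finite.size == 0 or vals[-1] > 1e-6 * vals.max():
            raise ValueError("autocorrelation does not decay; outer integral diverges")
        tau = float(finite[-1]) / 40.0
    horizon = 60.0 * tau

    def inner_D(s):
        return np.sum(w_k * np.cos(2 * np.pi * k * omega * s))

    def inner_v(s):
        return -np.sum(2 * np.pi * k * w_k * np.sin(2 * np.pi * k * omega * s))

    limit = 400
    d_half, _ = integrate.quad(
        lambda s: corr(s) * inner_D(s), 0.0, horizon, limit=limit,
        epsabs=1e-14, epsrel=1e-10,
    )
    v_val, _ = integrate.quad(
        lambda s: corr(s) * inner_v(s), 0.0, horizon, limit=limit,
        epsabs=1e-14, epsrel=1e-10,
    )
    D_C = sigma_C**2 * 2.0 * d_half  # C(s) and the inner integral are even in s
    v_C = sigma_C**2 * v_val
    return float(v_C), float(D_C)


# ---------------------------------------------------------------------------
# PRC and stimulus trains
# ---------------------------------------------------------------------------

def prc_lookup(params: PhaseModelParams, phi, beta: float):
    """Phase shift Delta(phi, beta) from the tabulated PRC.

    The table is stored at the reference perturbation ``beta_ref``; shifts
    scale linearly with beta / beta_ref (assumed linear response regime).
    """
    if beta <= 0:
        raise ValueError(f"impulse strength beta must be positive, got {beta}")
    return (beta / params.beta_ref) * periodic_interp(params.prc, phi)


def sample_stimulus_train(
    settings: StimulusSettings, duration: float, seed: int = 0,
    membrane_C: float = 1.0,
) -> StimulusTrain:
    """Poisson-parametrized impulse train with mean frequency f.

    Inter-impulse intervals are Delta_tau = X / (f * lam) with X ~ Poisson(lam)
    drawn independently per interval (zero draws redrawn), so the mean IPI is
    exactly 1/f and the IPI coefficient of variation is 1/sqrt(lam).  With
    lam = inf the train is perfectly regular (IPI = 1/f).  beta = w I0 / C.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    beta = settings.w * settings.I0 / membrane_C
    if duration < 1.0 / settings.f:
        warnings.warn(
            "duration shorter than one mean inter-impulse interval; the train "
            "may be empty", RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    times = []
    t = 0.0
    mean_ipi = 1.0 / settings.f
    while True:
        if np.isinf(settings.lam):
            ipi = mean_ipi
        else:
            x = 0
            while x == 0:
                x = int(rng.poisson(settings.lam))
            ipi = x / (settings.f * settings.lam)
        t += ipi
        if t > duration:
            break
        times.append(t)
    return StimulusTrain(tau_k=np.array(times), beta=beta, seed=seed)


# ---------------------------------------------------------------------------
# Euler-Maruyama integration
# ---------------------------------------------------------------------------

def _drift_diffusion(params: PhaseModelParams, phi, ito_literal: bool):
    """Vectorized drift and diffusion of the phase SDE at wrapped phases."""
    v_c, d_c = params.noise_coefficients()
    r_i = periodic_interp(params.R_I, phi)
    g = params.sigma_I * r_i + d_c
    drift = (
        params.omega
        + params.K * params.r * np.sin(2 * np.pi * (params.psi - phi + params.a))
        + v_c
    )
    if params.sigma_I > 0:
        r_ip = periodic_interp(params.R_I_prime, phi)
        factor = params.sigma_I**2 if ito_literal else params.sigma_I / 2.0
        drift = drift + factor * r_ip * g
    return drift, g


def simulate_phase_sde(
    params: PhaseModelParams,
    train: StimulusTrain | None,
    duration: float,
    dt: float = 1e-4,
    seed: int = 0,
    phi0: float = 0.0,
    ito_literal: bool = False,
) -> PhaseTrajectory:
    """Seeded Euler-Maruyama simulation of the phase SDE with impulse jumps.

    Impulses are applied at their exact times by step splitting: the enclosing
    step is cut at tau_k, the diffusion step is completed, then the PRC jump
    phi -> phi + Delta(phi, beta) is applied instantaneously.
    """
    if dt > 0.1 / max(params.omega, 1e-12):
        raise ValueError(f"dt={dt} too coarse for omega={params.omega} (need dt <= 0.1/omega)")
    if duration < dt:
        raise ValueError("duration must cover at least one step")
    v_c, d_c = params.noise_coefficients()
    rng = np.random.default_rng(seed)
    impulses = np.array([]) if train is None else train.tau_k
    impulses = impulses[(impulses > 0) & (impulses <= duration)]
    beta = None if train is None else train.beta

    n_steps = int(round(duration / dt))
    t_grid = np.arange(n_steps + 1) * dt
    phi_u = np.empty(n_steps + 1)
    phi_u[0] = phi0
    impulse_index = np.searchsorted(t_grid, impulses)

    noisy = params.sigma_I > 0 or d_c != 0.0
    next_imp = 0
    phi = float(phi0)

    def _advance(phi_val: float, step: float) -> float:
        drift, g = _drift_diffusion(params, phi_val % 1.0, ito_literal)
        incr = float(drift) * step
        if noisy:
            incr += float(g) * np.sqrt(step) * rng.standard_normal()
        return phi_val + incr

    for k in range(n_steps):
        t0, t1 = t_grid[k], t_grid[k + 1]
        cur = phi
        seg_start = t0
        while next_imp < impulses.size and impulses[next_imp] <= t1:
            t_imp = impulses[next_imp]
            if t_imp > seg_start:
                cur = _advance(cur, t_imp - seg_start)
            jump = prc_lookup(params, cur % 1.0, beta)
            cur = cur + float(jump)
            seg_start = t_imp
            next_imp += 1
        if t1 > seg_start:
            if seg_start == t0:
                cur = _advance(cur, dt)  # exact dt to keep noise-free runs crisp
            else:
                cur = _advance(cur, t1 - seg_start)
        if not np.isfinite(cur):
            raise FloatingPointError(
                f"non-finite phase at step {k} (t={t1:.6g} s)"
            )
        phi = cur
        phi_u[k + 1] = phi

    return PhaseTrajectory(
        t=t_grid, phi=phi_u % 1.0, phi_unwrapped=phi_u,
        impulse_index=impulse_index,
    )

def simulate_phase_ensemble(
    params: PhaseModelParams,
    n_paths: int,
    duration: float,
    dt: float = 1e-3,
    seed: int = 0,
    phi0=0.0,
    train: StimulusTrain | None = None,
    ito_literal: bool = False,
) -> np.ndarray:
    """Vectorized Euler-Maruyama ensemble; returns unwrapped phases.

    All paths share the impulse train (applied at the grid step containing
    each tau_k) but draw independent diffusion noise.  Returns an array of
    shape (n_steps + 1, n_paths); wrapped phases are ``result % 1``.
    """
    if dt > 0.1 / max(params.omega, 1e-12):
        raise ValueError(f"dt={dt} too coarse for omega={params.omega}")
    v_c, d_c = params.noise_coefficients()
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    phi = np.full(n_paths, phi0, dtype=float) if np.isscalar(phi0) else np.array(phi0, dtype=float)
    out = np.empty((n_steps + 1, n_paths))
    out[0] = phi
    impulses = np.array([]) if train is None else train.tau_k
    imp_steps = np.searchsorted(np.arange(1, n_steps + 1) * dt, impulses - 1e-12)
    noisy = params.sigma_I > 0 or d_c != 0.0
    sqdt = np.sqrt(dt)
    imp_ptr = 0
    for k in range(n_steps):
        drift, g = _drift_diffusion(params, phi % 1.0, ito_literal)
        phi = phi + drift * dt
        if noisy:
            phi = phi + g * sqdt * rng.standard_normal(n_paths)
        while imp_ptr < imp_steps.size and imp_steps[imp_ptr] == k:
            phi = phi + prc_lookup(params, phi % 1.0, train.beta)
            imp_ptr += 1
        out[k + 1] = phi
    if not np.all(np.isfinite(phi)):
        raise FloatingPointError("non-finite phase in ensemble integration")
    return out
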