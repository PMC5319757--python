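"""Perron-Frobenius approximation of the stimulus-to-stimulus phase map.

One application of the operator propagates the phase density across one
inter-impulse interval of the stimulation train, including the PRC jump of
the terminal impulse.  Discretizing the phase into m bins, the operator is
approximated by an m x m row-stochastic transition matrix built by per-bin
Monte-Carlo simulation of the phase SDE.  The dominant left eigenvector of
the matrix is the invariant density p_st; the variance of its elements,

    sigma^2_pst = (1/m) || p_st - mu_pst 1 ||_2^2,

is inversely related to the desynchronizing effect of the stimulation.  The
optimization cost adds a power penalty:

    F(x) = sigma^2_pst + g * P,   P = I0^2 * w * f * R,

with penalty weight g = 0.25 and electrode impedance R = 1000 ohm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from neuroloop.phase_model import (
    PhaseModelParams,
    StimulusSettings,
    _drift_diffusion,
    periodic_interp,
)

__all__ = [
    "TransitionMatrix",
    "InvariantDensity",
    "build_transition_matrix",
    "invariant_density",
    "density_variance",
    "stimulation_power",
    "cost_function",
]

DEFAULT_BINS = 500
DEFAULT_SAMPLES_PER_BIN = 500
POWER_PENALTY = 0.25
ELECTRODE_IMPEDANCE = 1000.0


@dataclass
class TransitionMatrix:
    """Row-stochastic m x m Monte-Carlo estimate of the phase-map kernel."""

    A: np.ndarray
    m: int
    n_samples_per_bin: int
    seed: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.m, self.m):
            raise ValueError("matrix shape does not match bin count")
        rowsum = self.A.sum(axis=1)
        if np.any(self.A < 0) or np.any(np.abs(rowsum - 1.0) > 1e-10):
            raise ValueError("matrix is not row-stochastic")


@dataclass
class InvariantDensity:
    """Stationary phase distribution of the transition matrix."""

    p_st: np.ndarray
    eigenvalue: float
    variance: float
    mu: float


def _sample_ipis(settings: StimulusSettings, n: int, rng) -> np.ndarray:
    """Inter-impulse intervals Delta_tau = X/(f lam), X ~ Poisson(lam) > 0."""
    if np.isinf(settings.lam):
        return np.full(n, 1.0 / settings.f)
    x = rng.poisson(settings.lam, size=n).astype(float)
    while True:
        zero = x == 0
        if not zero.any():
            break
        x[zero] = rng.poisson(settings.lam, size=int(zero.sum()))
    return x / (settings.f * settings.lam)


def build_transition_matrix(
    params: PhaseModelParams,
    settings: StimulusSettings,
    m: int = DEFAULT_BINS,
    n_samples_per_bin: int = DEFAULT_SAMPLES_PER_BIN,
    seed: int = 0,
    dt: float = 1e-3,
) -> TransitionMatrix:
    """Monte-Carlo transition matrix of the one-impulse-cycle phase map.

    For each starting bin, ``n_samples_per_bin`` phase-SDE paths are launched
    from the bin center, integrated across one sampled inter-impulse interval
    and given the terminal impulse's PRC jump; row i is the normalized
    histogram of arrival bins.  Inter-impulse intervals and diffusion noise
    come from separate child streams of ``seed`` so that repeated evaluations
    with the same seed share their random numbers across different settings
    (common random numbers, reducing optimizer-visible Monte-Carlo noise).
    """
    if n_samples_per_bin < 1:
        raise ValueError("n_samples_per_bin must be positive")
    rng_ipi = np.random.default_rng([seed, 1])
    rng_noise = np.random.default_rng([seed, 2])
    v_c, d_c = params.noise_coefficients()
    beta = settings.w * settings.I0 / params.membrane_C

    n_total = m * n_samples_per_bin
    centers = (np.arange(m) + 0.5) / m
    phi = np.repeat(centers, n_samples_per_bin)

    ipi = _sample_ipis(settings, n_total, rng_ipi)
    full_steps = np.floor(ipi / dt).astype(int)
    remainder = ipi - full_steps * dt
    max_steps = int(full_steps.max())

    noisy = params.sigma_I > 0 or d_c != 0.0
    sqdt = np.sqrt(dt)
    for k in range(max_steps):
        active = k < full_steps
        drift, g = _drift_diffusion(params, phi % 1.0, False)
        incr = drift * dt
        if noisy:
            incr = incr + g * sqdt * rng_noise.standard_normal(n_total)
        phi = np.where(active, phi + incr, phi)
    # fractional last step of per-sample length remainder
    pos_rem = remainder > 0
    if pos_rem.any():
        drift, g = _drift_diffusion(params, phi % 1.0, False)
        incr = drift * remainder
        if noisy:
            incr = incr + g * np.sqrt(remainder) * rng_noise.standard_normal(n_total)
        phi = np.where(pos_rem, phi + incr, phi)
    # terminal impulse of the cycle
    phi = phi + (beta / params.beta_ref) * periodic_interp(params.prc, phi % 1.0)
    if not np.all(np.isfinite(phi)):
        raise FloatingPointError("non-finite phase during kernel construction")

    arrival = np.floor((phi % 1.0) * m).astype(int) % m
    A = np.zeros((m, m))
    rows = np.repeat(np.arange(m), n_samples_per_bin)
    np.add.at(A, (rows, arrival), 1.0)
    A /= n_samples_per_bin
    return TransitionMatrix(A=A, m=m, n_samples_per_bin=n_samples_per_bin, seed=seed)


def invariant_density(A: TransitionMatrix) -> InvariantDensity:
    """Dominant left eigenvector of the transition matrix (p_st A = p_st).

    The eigensolver result is polished by power iteration and validated as a
    fixed point; an eigenvalue degenerate at 1 raises an error.
    """
    mat = A.A
    vals, vecs = linalg.eig(mat.T)
    order = np.argsort(-vals.real)
    lead = vals[order[0]]
    if abs(lead - 1.0) > 1e-6:
        raise ValueError(f"dominant eigenvalue {lead} is not 1")
    if len(order) > 1 and abs(vals[order[1]] - 1.0) < 1e-8:
        raise ValueError("dominant unit eigenvalue has multiplicity > 1")
    p = np.real(vecs[:, order[0]])
    if p.sum() < 0:
        p = -p
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    # polish: a few power iterations remove eigensolver noise
    for _ in range(200):
        p_next = p @ mat
        if np.abs(p_next - p).sum() < 1e-14:
            p = p_next
            break
        p = p_next
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    var = density_variance(p, A.m)
    return InvariantDensity(
        p_st=p, eigenvalue=float(lead.real), variance=var, mu=float(p.mean())
    )


def density_variance(p_st: np.ndarray, m: int | None = None) -> float:
    """Variance of the invariant-density elements, (1/m)||p - mu 1||_2^2."""
    p = np.asarray(p_st, dtype=float)
    m = p.size if m is None else m
    mu = p.mean()
    return float(np.sum((p - mu) ** 2) / m)


def stimulation_power(
    settings: StimulusSettings, R: float = ELECTRODE_IMPEDANCE
) -> float:
    """Stimulation power P = I0^2 * w * f * R in watts (w converted to s)."""
    return settings.I0**2 * (settings.w * 1e-6) * settings.f * R


def cost_function(
    settings: StimulusSettings,
    params: PhaseModelParams,
    m: int = DEFAULT_BINS,
    n_samples_per_bin: int = DEFAULT_SAMPLES_PER_BIN,
    seed: int = 0,
    g: float = POWER_PENALTY,
    R: float = ELECTRODE_IMPEDANCE,
    dt: float = 1e-3,
) -> float:
    """Power-penalized invariant-density cost F(x) = sigma^2_pst + g P.

    The same ``seed`` must be reused across evaluations within one
    optimization run (common random numbers).
    """
    A = build_transition_matrix(
        params, settings, m=m, n_samples_per_bin=n_samples_per_bin,
        seed=seed, dt=dt,
    )
    dens = invariant_density(A)
    return dens.variance + g * stimulation_power(settings, R=R)
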