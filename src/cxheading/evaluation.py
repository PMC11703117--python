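"""Quantitative evaluation protocols: integration accuracy, attractor stability.

Three perturbation families probe the trained circuit:

* zero-mean Gaussian membrane noise (mV) added to the steady-state
  potential of every columnar neuron each millisecond;
* Beta-distributed resampling of the synaptic open probabilities each
  millisecond (mean equal to the noise-free value, spread set by a
  pseudocount) — range-limited to [0, 1] so the sample stays a
  probability;
* uniform multiplicative weight noise, drawn once per trial,
  proportional to each weight (modulatory weights included).

Integration accuracy is the angular error between the decoded and true
heading after 4 s of low-pass-filtered Gaussian angular-velocity input;
attractor stability is the residual of the best-fitting cosine to the
CL1a activity 100 ms after a perturbed initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .circuit import (
    N_COLUMNAR,
    WeightSet,
    av_rates,
    cosine_fit,
    encode_heading,
    wrap_deg,
)
from .dynamics import CircuitDynamics, synapse_fixed_point

__all__ = [
    "NoiseConfig",
    "TrajectoryParams",
    "angular_error",
    "generate_av_trajectory",
    "run_integration_suite",
    "run_attractor_suite",
    "IntegrationSuiteResult",
    "AttractorSuiteResult",
]


def angular_error(phi, phi_est):
    """Absolute circular distance in degrees, in [0, 180]; symmetric."""
    phi = np.asarray(phi, dtype=float)
    phi_est = np.asarray(phi_est, dtype=float)
    out = np.abs(np.mod(phi - phi_est + 180.0, 360.0) - 180.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NoiseConfig:
    """Perturbation levels for the evaluation suites.

    ``sigma_u`` is the membrane-noise SD in mV; ``release_pseudocount``
    the Beta pseudocount for open-probability noise (``None`` disables
    it; smaller pseudocount means more noise); ``weight_noise_range``
    the half-width of the per-trial multiplicative weight jitter;
    ``presyn_rate_sigma_rel`` the initial presynaptic-rate perturbation
    SD relative to the bump amplitude (attractor suite only).
    """

    sigma_u: float = 0.0
    release_pseudocount: Optional[float] = None
    weight_noise_range: float = 0.0
    presyn_rate_sigma_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.weight_noise_range < 0:
            raise ValueError("noise levels must be non-negative")
        if self.presyn_rate_sigma_rel < 0:
            raise ValueError("noise levels must be non-negative")
        if self.release_pseudocount is not None and self.release_pseudocount < 2:
            raise ValueError(
                "pseudocount must be >= 2 for well-defined Beta shapes"
            )


@dataclass(frozen=True)
class TrajectoryParams:
    """Low-pass-filtered Gaussian angular-velocity generator settings.

    A first-order (exponential-smoothing) filter applied to white
    Gaussian noise — an Ornstein-Uhlenbeck process sampled at ``dt`` —
    with correlation time ``tau_ms``, stationary standard deviation
    ``sigma`` (deg/s) and hard clipping at ``v_clip``. The defaults give
    a zero-mean meandering rotation bounded by the circuit's +-150 deg/s
    range, emulating the rotational trajectories of walking locusts.
    """

    tau_ms: float = 500.0
    sigma: float = 50.0
    v_clip: float = 150.0
    dt: float = 1.0


def generate_av_trajectory(
    duration_ms: float,
    seed_or_rng,
    params: TrajectoryParams = TrajectoryParams(),
    n_trials: Optional[int] = None,
) -> np.ndarray:
    """Zero-mean, temporally correlated angular-velocity series (deg/s).

    Returns shape ``(n_steps,)`` or ``(n_trials, n_steps)``; one sample
    per ``params.dt`` ms, clipped to +-``v_clip``. The generator starts
    from its stationary distribution, so the series is stationary and
    reproducible given the seed.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = int(round(duration_ms / params.dt))
    b = 1 if n_trials is None else n_trials
    rho = np.exp(-params.dt / params.tau_ms)
    innov_sd = params.sigma * np.sqrt(1.0 - rho**2)
    v = np.empty((b, n))
    state = rng.normal(0.0, params.sigma, size=b)
    for i in range(n):
        v[:, i] = state
        state = rho * state + rng.normal(0.0, innov_sd, size=b)
    np.clip(v, -params.v_clip, params.v_clip, out=v)
    return v[0] if n_trials is None else v


# ---------------------------------------------------------------------------
# batched noisy forward simulation
# ---------------------------------------------------------------------------

def _make_engine(
    weights: WeightSet,
    noise: NoiseConfig,
    rng: np.random.Generator,
    n_trials: int,
    constants: ModelConstants,
) -> CircuitDynamics:
    """Engine with per-trial multiplicative weight noise when requested."""
    if noise.weight_noise_range > 0.0:
        def jitter(m):
            f = rng.uniform(
                1.0 - noise.weight_noise_range,
                1.0 + noise.weight_noise_range,
                size=(n_trials,) + m.shape,
            )
            return f * m[None, :, :]

        return CircuitDynamics(
            jitter(weights.g_s),
            jitter(weights.g_mod_cw),
            jitter(weights.g_mod_ccw),
            constants,
        )
    return weights.dynamics(constants)


def _run_batch(
    engine: CircuitDynamics,
    ps: np.ndarray,
    prel: np.ndarray,
    v: np.ndarray,
    noise: NoiseConfig,
    rng: np.random.Generator,
    constants: ModelConstants,
    dt: float = 1.0,
) -> tuple:
    """Integrate a batch of trials; returns final (ps, prel).

    ``v`` has shape (B, n_steps) in deg/s and is held constant within
    each step. Membrane and open-probability noise are redrawn every
    step; the Beta perturbation enters the conductances without
    altering the synaptic state itself.
    """
    b, n_steps = v.shape
    r_cw, r_ccw = av_rates(v, constants)
    m_all = np.stack([r_cw, r_ccw], axis=2) / constants.r_av_max
    nu = noise.release_pseudocount
    for i in range(n_steps):
        u_noise = (
            rng.normal(0.0, noise.sigma_u, size=(b, N_COLUMNAR))
            if noise.sigma_u > 0.0
            else None
        )
        ps_delta = None
        if nu is not None:
            mu = np.clip(ps, 1e-9, 1.0 - 1e-9)
            ps_delta = rng.beta(nu * mu, nu * (1.0 - mu)) - ps
        ps, prel = engine.rk4_step(ps, prel, m_all[:, i], dt, u_noise, ps_delta)
    return ps, prel


# ---------------------------------------------------------------------------
# integration-accuracy suite
# ---------------------------------------------------------------------------

@dataclass
class IntegrationSuiteResult:
    """Per-trial final angular errors (deg) of one noise condition."""

    errors: np.ndarray
    noise: NoiseConfig
    n_trials: int
    duration_ms: float

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def sem(self) -> float:
        return float(self.errors.std(ddof=1) / np.sqrt(self.errors.size))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.errors.size),
                "sigma_u_mv": self.noise.sigma_u,
                "release_pseudocount": self.noise.release_pseudocount,
                "weight_noise_range": self.noise.weight_noise_range,
                "final_error_deg": self.errors,
            }
        )


def run_integration_suite(
    weights: WeightSet,
    noise: NoiseConfig = NoiseConfig(),
    n_trials: int = 2000,
    duration_ms: float = 4000.0,
    constants: ModelConstants = ModelConstants(),
    trajectory: TrajectoryParams = TrajectoryParams(),
    dt: float = 1.0,
) -> IntegrationSuiteResult:
    """Angular-velocity integration accuracy under noise.

    Each trial starts from a random heading, receives low-pass-filtered
    Gaussian angular-velocity input for ``duration_ms`` and reports the
    angular error between the decoded and true final heading. The true
    heading integrates exactly the piecewise-constant input the circuit
    receives.
    """
    rng = np.random.default_rng(noise.seed)
    phi0 = rng.uniform(0.0, 360.0, size=n_trials)
    v = generate_av_trajectory(duration_ms, rng, trajectory, n_trials=n_trials)

    bump = encode_heading(phi0, constants)
    presyn = np.concatenate(
        [bump, bump, np.full((n_trials, 1), constants.r_bias)], axis=1
    )
    ps = synapse_fixed_point(presyn, constants)
    prel = np.zeros((n_trials, 2))

    engine = _make_engine(weights, noise, rng, n_trials, constants)
    ps, prel = _run_batch(engine, ps, prel, v, noise, rng, constants, dt)

    r_final = 1000.0 * engine.rates_khz(ps, prel)
    phase, _, _ = cosine_fit(r_final[:, :16])
    phi_true = wrap_deg(phi0 + np.sum(np.clip(v, -150, 150), axis=1) * dt / 1000.0)
    errors = angular_error(phi_true, phase)
    return IntegrationSuiteResult(errors, noise, n_trials, duration_ms)


# ---------------------------------------------------------------------------
# attractor-stability suite
# ---------------------------------------------------------------------------

@dataclass
class AttractorSuiteResult:
    """Initial and final cosine-fit residuals of one noise condition.

    ``rmse`` values are relative: residual RMS divided by the RMS of
    the (mean-removed) fitted cosine, so 0 is a perfect sinusoid and 1
    means the residual is as large as the signal.
    """

    initial_rmse: np.ndarray
    final_rmse: np.ndarray
    noise: NoiseConfig
    n_trials: int
    duration_ms: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.final_rmse.size),
                "presyn_rate_sigma_rel": self.noise.presyn_rate_sigma_rel,
                "weight_noise_range": self.noise.weight_noise_range,
                "initial_rmse": self.initial_rmse,
                "final_rmse": self.final_rmse,
            }
        )


def relative_cosine_rmse(rates: np.ndarray) -> np.ndarray:
    """Residual RMS of the best-fitting cosine, relative to the signal RMS."""
    _, amplitude, resid_rms = cosine_fit(rates)
    signal_rms = amplitude / np.sqrt(2.0)
    return resid_rms / np.maximum(signal_rms, 1e-12)


def run_attractor_suite(
    weights: WeightSet,
    noise: NoiseConfig = NoiseConfig(),
    n_trials: int = 1000,
    duration_ms: float = 100.0,
    constants: ModelConstants = ModelConstants(),
    trajectory: TrajectoryParams = TrajectoryParams(),
    dt: float = 1.0,
) -> AttractorSuiteResult:
    """Stability of the compass state against a perturbed initialisation.

    Gaussian noise with SD ``presyn_rate_sigma_rel x bump amplitude``
    is added to the initial presynaptic columnar rates (which also seed
    the synaptic fixed points); the circuit then runs for
    ``duration_ms`` under low-pass-filtered angular-velocity input, and
    the relative residual of the best-fitting cosine to the final CL1a
    activity is reported per trial.
    """
    rng = np.random.default_rng(noise.seed)
    phi0 = rng.uniform(0.0, 360.0, size=n_trials)
    v = generate_av_trajectory(duration_ms, rng, trajectory, n_trials=n_trials)

    bump = encode_heading(phi0, constants)
    sigma = noise.presyn_rate_sigma_rel * constants.bump_amplitude
    noisy = np.maximum(
        np.concatenate([bump, bump], axis=1)
        + rng.normal(0.0, sigma, size=(n_trials, N_COLUMNAR)),
        0.0,
    )
    initial_rmse = relative_cosine_rmse(noisy[:, :16])

    presyn = np.concatenate([noisy, np.full((n_trials, 1), constants.r_bias)], axis=1)
    ps = synapse_fixed_point(presyn, constants)
    prel = np.zeros((n_trials, 2))

    engine = _make_engine(weights, noise, rng, n_trials, constants)
    ps, prel = _run_batch(engine, ps, prel, v, noise, rng, constants, dt)

    r_final = 1000.0 * engine.rates_khz(ps, prel)
    final_rmse = relative_cosine_rmse(r_final[:, :16])
    return AttractorSuiteResult(initial_rmse, final_rmse, noise, n_trials, duration_ms)
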