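"""Single-neuron and synapse equations, and the batched RK4 circuit core.

The model is a network of steady-state firing-rate neurons: membrane
potentials equilibrate instantaneously on the time scale of the synapses,
so rates are algebraic functions of the synaptic state and only the
synaptic open probabilities ``P_s`` (one per pre-synaptic neuron) and the
modulatory release probabilities ``P_rel`` (one per angular-velocity
neuron) are integrated.

Public element-wise operations (:func:`firing_rate`,
:func:`steady_state_potential`, ...) validate their arguments and work in
interface units (Hz, mV, ms). The :class:`CircuitDynamics` engine is the
vectorised hot path used by simulation and training; it works in spikes
per millisecond internally and skips per-call validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .constants import ModelConstants
from .exceptions import DegenerateCircuitError

__all__ = [
    "firing_rate",
    "total_conductance",
    "steady_state_potential",
    "synapse_derivative",
    "release_derivative",
    "synapse_fixed_point",
    "CircuitDynamics",
    "DriftCache",
]

#: guard on the denominator of the steady-state potential
DENOMINATOR_EPS = 1e-3


# ---------------------------------------------------------------------------
# element-wise operations (interface units)
# ---------------------------------------------------------------------------

def firing_rate(u_inf, constants: ModelConstants = ModelConstants()):
    """Logistic rate function: membrane potential (mV) -> rate (Hz).

    ``r = r_max / (1 + exp(-slope * (U_inf - half_point)))``; the output is
    strictly inside ``(0, r_max)`` for finite input.
    """
    u = np.asarray(u_inf, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("firing_rate requires finite membrane potentials")
    r = constants.r_max * expit(constants.slope * (u - constants.half_point))
    return float(r) if np.isscalar(u_inf) else r


def total_conductance(g_s, g_mod, p_rel):
    """Total relative conductance ``g_tot = g_s + sum_j P_rel[j] * g_mod[j]``.

    ``g_mod`` and ``p_rel`` enumerate the modulatory inputs of the synapse
    and must have matching shapes.
    """
    g_mod = np.asarray(g_mod, dtype=float)
    p_rel = np.asarray(p_rel, dtype=float)
    if g_mod.shape != p_rel.shape:
        raise ValueError(
            f"shape mismatch: g_mod {g_mod.shape} vs p_rel {p_rel.shape}"
        )
    if p_rel.size and (p_rel.min() < 0.0 or p_rel.max() > 1.0):
        raise ValueError("release probabilities must lie in [0, 1]")
    return float(g_s + np.sum(p_rel * g_mod))


def steady_state_potential(g_tot, p_s, e_s, eps: float = DENOMINATOR_EPS):
    """Steady-state membrane potential (mV) of a shunting conductance model.

    ``U_inf = sum(g_tot * P_s * E_s) / (1 + sum(g_tot * P_s))``. The empty
    sum gives 0 mV; a denominator at or below ``eps`` raises
    :class:`~cxheading.exceptions.DegenerateCircuitError`.
    """
    g_tot = np.atleast_1d(np.asarray(g_tot, dtype=float))
    p_s = np.atleast_1d(np.asarray(p_s, dtype=float))
    e_s = np.atleast_1d(np.asarray(e_s, dtype=float))
    gp = g_tot * p_s
    den = 1.0 + gp.sum()
    if den <= eps:
        raise DegenerateCircuitError(
            f"steady-state denominator {den:.3g} <= eps={eps:g}"
        )
    return float((gp * e_s).sum() / den)


def synapse_derivative(p_s, r_pre, constants: ModelConstants = ModelConstants()):
    """Time derivative (1/ms) of the synaptic open probability.

    ``dP_s/dt = P_s_max * r - (r + 1/tau_s) * P_s`` with the pre-synaptic
    rate ``r_pre`` given in Hz and converted to spikes/ms internally.
    """
    r = np.asarray(r_pre, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("pre-synaptic rates must be non-negative")
    r_khz = r / 1000.0
    out = constants.P_s_max * r_khz - (r_khz + 1.0 / constants.tau_s) * np.asarray(
        p_s, dtype=float
    )
    return float(out) if np.isscalar(p_s) and np.isscalar(r_pre) else out


def release_derivative(p_rel, r_mod, constants: ModelConstants = ModelConstants()):
    """Time derivative (1/ms) of the modulatory release probability.

    First-order relaxation of ``P_rel`` toward ``r_mod / r_av_max`` with
    time constant ``tau_s_mod``; at the fixed point the release probability
    is proportional to the modulatory rate and stays in [0, 1].
    """
    r = np.asarray(r_mod, dtype=float)
    if np.any(r < 0.0) or np.any(r > constants.r_av_max):
        raise ValueError(f"modulatory rate must lie in [0, {constants.r_av_max}] Hz")
    out = (r / constants.r_av_max - np.asarray(p_rel, dtype=float)) / constants.tau_s_mod
    return float(out) if np.isscalar(p_rel) and np.isscalar(r_mod) else out


def synapse_fixed_point(r_pre, constants: ModelConstants = ModelConstants()):
    """Stationary open probability ``r / (r + 1/tau_s)`` for a constant rate (Hz)."""
    r_khz = np.asarray(r_pre, dtype=float) / 1000.0
    return r_khz / (r_khz + 1.0 / constants.tau_s)


# ---------------------------------------------------------------------------
# batched circuit core
# ---------------------------------------------------------------------------

@dataclass
class DriftCache:
    """Intermediates of one drift evaluation, kept for the backward pass."""

    ps_used: np.ndarray      # (B, n_pre) open probabilities entering conductances
    ps_state: np.ndarray     # (B, n_pre) state open probabilities
    c_cw: np.ndarray         # (B,) clockwise release probability
    c_ccw: np.ndarray        # (B,) counterclockwise release probability
    den: np.ndarray          # (B, n_post) 1 + S
    r_khz: np.ndarray        # (B, n_post) columnar rates, spikes/ms


class CircuitDynamics:
    """Vectorised drift, rate read-out and RK4 stepping for a weight set.

    Parameters
    ----------
    g_s, g_cw, g_ccw:
        Dense weight matrices of shape ``(n_post, n_pre)`` (the
        unmodulated weights and the modulatory weights of the clockwise
        and counterclockwise angular-velocity neurons). A leading batch
        axis ``(B, n_post, n_pre)`` is accepted for per-trial perturbed
        weights.
    constants:
        Model constants; rates are converted to spikes/ms internally.
    """

    def __init__(
        self,
        g_s: np.ndarray,
        g_cw: np.ndarray,
        g_ccw: np.ndarray,
        constants: ModelConstants,
        eps: float = DENOMINATOR_EPS,
    ) -> None:
        self.g_s = np.asarray(g_s, dtype=float)
        self.g_cw = np.asarray(g_cw, dtype=float)
        self.g_ccw = np.asarray(g_ccw, dtype=float)
        if self.g_s.shape != self.g_cw.shape or self.g_s.shape != self.g_ccw.shape:
            raise ValueError("weight matrices must share one shape")
        self.batched_weights = self.g_s.ndim == 3
        self.n_post = self.g_s.shape[-2]
        self.n_pre = self.g_s.shape[-1]
        self.c = constants
        self.eps = eps
        self._r_max_khz = constants.r_max / 1000.0
        self._r_bias_khz = constants.r_bias / 1000.0
        self._inv_tau_s = 1.0 / constants.tau_s
        self._inv_tau_mod = 1.0 / constants.tau_s_mod

    # -- forward ------------------------------------------------------------

    def _conductance_sum(self, ps: np.ndarray, c_cw: np.ndarray, c_ccw: np.ndarray):
        """S_i = sum_pre g_tot[i, pre] * P_s[pre] for every post neuron."""
        if self.batched_weights:
            s = np.einsum("bij,bj->bi", self.g_s, ps)
            s += c_cw[:, None] * np.einsum("bij,bj->bi", self.g_cw, ps)
            s += c_ccw[:, None] * np.einsum("bij,bj->bi", self.g_ccw, ps)
        else:
            s = ps @ self.g_s.T
            s += c_cw[:, None] * (ps @ self.g_cw.T)
            s += c_ccw[:, None] * (ps @ self.g_ccw.T)
        return s

    def rates_khz(
        self,
        ps: np.ndarray,
        prel: np.ndarray,
        u_noise: Optional[np.ndarray] = None,
        ps_delta: Optional[np.ndarray] = None,
        want_cache: bool = False,
    ):
        """Algebraic columnar rates (spikes/ms) for synaptic state (ps, prel).

        ``u_noise`` (mV, per post neuron) perturbs the steady-state
        potential before the rate nonlinearity; ``ps_delta`` perturbs the
        open probabilities entering the conductances (but not the state).
        """
        ps_used = ps if ps_delta is None else ps + ps_delta
        c_cw = prel[:, 0]
        c_ccw = prel[:, 1]
        s = self._conductance_sum(ps_used, c_cw, c_ccw)
        den = 1.0 + s
        if den.min() <= self.eps:
            raise DegenerateCircuitError(
                f"steady-state denominator fell to {den.min():.3g}"
            )
        u = self.c.E_ex * s / den
        if u_noise is not None:
            u = u + u_noise
        x = self.c.slope * (u - self.c.half_point)
        r = self._r_max_khz * expit(x)
        if want_cache:
            return r, DriftCache(ps_used, ps, c_cw, c_ccw, den, r)
        return r

    def drift(
        self,
        ps: np.ndarray,
        prel: np.ndarray,
        m_target: np.ndarray,
        u_noise: Optional[np.ndarray] = None,
        ps_delta: Optional[np.ndarray] = None,
        want_cache: bool = False,
    ):
        """Time derivatives (1/ms) of ``P_s`` (B, n_pre) and ``P_rel`` (B, 2).

        ``m_target`` is the pair of normalised angular-velocity drives
        ``r_AV / r_AV_max`` in [0, 1], shape (B, 2).
        """
        out = self.rates_khz(ps, prel, u_noise, ps_delta, want_cache)
        r, cache = out if want_cache else (out, None)
        r_full = np.concatenate(
            [r, np.full((r.shape[0], 1), self._r_bias_khz)], axis=1
        )
        dps = self.c.P_s_max * r_full - (r_full + self._inv_tau_s) * ps
        dprel = (m_target - prel) * self._inv_tau_mod
        if want_cache:
            return dps, dprel, cache
        return dps, dprel

    def rk4_step(
        self,
        ps: np.ndarray,
        prel: np.ndarray,
        m_target: np.ndarray,
        dt: float,
        u_noise: Optional[np.ndarray] = None,
        ps_delta: Optional[np.ndarray] = None,
    ):
        """One 4th-order Runge-Kutta step of the synaptic state.

        Probabilities are clamped to [0, 1] after the update. The
        angular-velocity drive and any noise sample are held constant
        across the four stages (zero-order hold within the step).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        half = 0.5 * dt
        k1p, k1c = self.drift(ps, prel, m_target, u_noise, ps_delta)
        k2p, k2c = self.drift(ps + half * k1p, prel + half * k1c, m_target, u_noise, ps_delta)
        k3p, k3c = self.drift(ps + half * k2p, prel + half * k2c, m_target, u_noise, ps_delta)
        k4p, k4c = self.drift(ps + dt * k3p, prel + dt * k3c, m_target, u_noise, ps_delta)
        ps_new = ps + (dt / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        prel_new = prel + (dt / 6.0) * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        np.clip(ps_new, 0.0, 1.0, out=ps_new)
        np.clip(prel_new, 0.0, 1.0, out=prel_new)
        return ps_new, prel_new

    # -- backward (used by training) ----------------------------------------

    def drift_vjp(self, cache: DriftCache, g_dps: np.ndarray):
        """Vector-Jacobian product of :meth:`drift` w.r.t. ``P_s``.

        Given the cotangent ``g_dps`` of the ``dP_s/dt`` output, returns
        ``(a_ps, g_s_cot)`` where ``a_ps`` is the cotangent of the input
        ``P_s`` and ``g_s_cot`` (B, n_post) is the cotangent of the
        conductance sums ``S``, from which the caller accumulates weight
        gradients (``dL/dG[i, pre] += g_s_cot[i] * ps_used[pre]``).

        ``P_rel`` carries no weight dependence, so its adjoint is dropped.
        """
        r = cache.r_khz
        # dP_s/dt = r_full - (r_full + 1/tau_s) * ps: route through r then U, S
        g_r = g_dps[:, : self.n_post] * (
            self.c.P_s_max - cache.ps_state[:, : self.n_post]
        )
        dr_du = self.c.slope * r * (1.0 - r / self._r_max_khz)
        g_u = g_r * dr_du
        g_s_cot = g_u * (self.c.E_ex / cache.den**2)
        a_ps = self._conductance_sum_t(g_s_cot, cache.c_cw, cache.c_ccw)
        r_full = np.concatenate(
            [r, np.full((r.shape[0], 1), self._r_bias_khz)], axis=1
        )
        a_ps = a_ps - (r_full + self._inv_tau_s) * g_dps
        return a_ps, g_s_cot

    def rates_vjp(self, cache: DriftCache, g_r_khz: np.ndarray):
        """Vector-Jacobian product of :meth:`rates_khz` w.r.t. ``P_s``."""
        r = cache.r_khz
        dr_du = self.c.slope * r * (1.0 - r / self._r_max_khz)
        g_u = g_r_khz * dr_du
        g_s_cot = g_u * (self.c.E_ex / cache.den**2)
        a_ps = self._conductance_sum_t(g_s_cot, cache.c_cw, cache.c_ccw)
        return a_ps, g_s_cot

    def _conductance_sum_t(self, g_s_cot, c_cw, c_ccw):
        """Transpose of :meth:`_conductance_sum` (cotangent of ``P_s``)."""
        if self.batched_weights:
            a = np.einsum("bij,bi->bj", self.g_s, g_s_cot)
            a += np.einsum("bij,bi->bj", self.g_cw, c_cw[:, None] * g_s_cot)
            a += np.einsum("bij,bi->bj", self.g_ccw, c_ccw[:, None] * g_s_cot)
        else:
            a = g_s_cot @ self.g_s
            a += (c_cw[:, None] * g_s_cot) @ self.g_cw
            a += (c_ccw[:, None] * g_s_cot) @ self.g_ccw
        return a
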