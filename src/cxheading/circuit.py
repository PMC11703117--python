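"""The 34-neuron heading circuit: connectivity, state, simulation, decoding.

The circuit comprises 16 CL1a-neurons (heading-encoding columnar neurons,
one per protocerebral-bridge column L8..R8), 16 CL2-neurons (columnar
neurons inheriting heading and carrying turn sensitivity), two
angular-velocity neurons (clockwise / counterclockwise) that act purely
through neuromodulation, and one bias neuron firing at a constant rate.

Columns are indexed 0..15 from L8 to R8; the preferred heading of column
``k`` is ``k * 22.5`` degrees. Along the lower central body (CBL), the
projections of left- and right-hemisphere neurons interleave, which is
captured here by the column map ``c(k) = 2 * (k mod 8) + (k div 8)``: two
intercalated 180-degree representations of azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import ModelConstants
from .dynamics import CircuitDynamics, synapse_fixed_point
from .exceptions import UndefinedPhaseError

__all__ = [
    "N_COLUMNS",
    "N_COLUMNAR",
    "N_PRE",
    "PHI_PREF_DEG",
    "neuron_names",
    "wrap_deg",
    "ConnectivityMask",
    "build_columnar_mask",
    "WeightSet",
    "CircuitState",
    "av_rates",
    "init_state",
    "simulate",
    "SimulationResult",
    "decode_heading",
    "cosine_fit",
]

N_COLUMNS = 16
N_COLUMNAR = 32          # 16 CL1a + 16 CL2 (postsynaptic axis)
N_PRE = 33               # columnar neurons + bias (presynaptic axis)
BIAS_INDEX = 32
CL1A = slice(0, 16)
CL2 = slice(16, 32)

#: preferred heading direction of PB column k, degrees
PHI_PREF_DEG = np.arange(N_COLUMNS) * 22.5


def _column_label(k: int) -> str:
    return f"L{8 - k}" if k < 8 else f"R{k - 7}"


def neuron_names(include_bias: bool = True) -> list:
    """Names of the columnar neurons (plus bias) in presynaptic axis order."""
    names = [f"CL1a_{_column_label(k)}" for k in range(N_COLUMNS)]
    names += [f"CL2_{_column_label(k)}" for k in range(N_COLUMNS)]
    if include_bias:
        names.append("BIAS")
    return names


def wrap_deg(phi):
    """Wrap angles to the half-open interval [0, 360)."""
    return np.mod(phi, 360.0)


def cbl_column(k):
    """CBL column of PB column ``k`` under the intercalated projection."""
    k = np.asarray(k)
    return 2 * (k % 8) + k // 8


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityMask:
    """Boolean structure of permitted synapses.

    ``ff_mask`` has shape (32, 33): postsynaptic columnar neurons by
    presynaptic columnar neurons plus the bias column. ``mod_mask`` (same
    shape) marks which of those synapses the two angular-velocity neurons
    may modulate; it is always a subset of ``ff_mask`` and never includes
    bias synapses.
    """

    ff_mask: np.ndarray
    mod_mask: np.ndarray

    def __post_init__(self) -> None:
        ff = np.asarray(self.ff_mask, dtype=bool)
        mod = np.asarray(self.mod_mask, dtype=bool)
        if ff.shape != (N_COLUMNAR, N_PRE) or mod.shape != (N_COLUMNAR, N_PRE):
            raise ValueError("masks must have shape (32, 33)")
        if np.any(mod & ~ff):
            raise ValueError("mod_mask must be a subset of ff_mask")
        object.__setattr__(self, "ff_mask", ff)
        object.__setattr__(self, "mod_mask", mod)

    @property
    def n_ff(self) -> int:
        return int(self.ff_mask.sum())

    @property
    def n_mod(self) -> int:
        return int(self.mod_mask.sum())

    @property
    def n_free_parameters(self) -> int:
        """Unmodulated weights plus one modulatory weight per AV neuron."""
        return self.n_ff + 2 * self.n_mod

    def restrict_modulation(self, population: str) -> "ConnectivityMask":
        """Limit modulation to synapses onto one columnar population.

        ``population`` is ``"both"`` (no restriction), ``"cl1a"`` or
        ``"cl2"``; restriction acts on the postsynaptic (row) identity.
        """
        population = population.lower()
        if population == "both":
            return self
        mod = self.mod_mask.copy()
        if population == "cl1a":
            mod[CL2, :] = False
        elif population == "cl2":
            mod[CL1A, :] = False
        else:
            raise ValueError(f"unknown population {population!r}")
        return ConnectivityMask(self.ff_mask, mod)


def build_columnar_mask(
    cl2_to_cl1a_pairs: Optional[Sequence] = None,
) -> ConnectivityMask:
    """Anatomically derived mask of permitted synapses.

    Encodes the five connectivity rules of the model:

    1. each CL1a-neuron may drive the CL2-neuron of its own PB column;
    2. each CL2-neuron may drive the CL1a pair sharing its CBL column:
       the ipsilateral same-column neuron and the contralateral
       (antipodal, ``k + 8``) one — overridable via
       ``cl2_to_cl1a_pairs``, a sequence of (post CL1a column, pre CL2
       column) index pairs;
    3. CL1a-neurons whose CBL arbors overlap (central column plus up to
       two flanking columns on either side, both hemispheres, including
       self-connections) may connect;
    4. CL2-neurons sharing a lower-nodulus hemisphere group (PB columns
       0..7 and 8..15) are all-to-all connected, including self;
    5. the bias neuron may drive every columnar neuron.

    Angular-velocity neurons may modulate every synapse among CL1a- and
    CL2-neurons (all of the above except the bias synapses).
    """
    ff = np.zeros((N_COLUMNAR, N_PRE), dtype=bool)
    k = np.arange(N_COLUMNS)

    # 1. CL1a_k -> CL2_k in the PB
    ff[16 + k, k] = True

    # 2. CL2 -> CL1a in the CBL
    if cl2_to_cl1a_pairs is None:
        cl2_to_cl1a_pairs = [(kk, kk) for kk in range(N_COLUMNS)] + [
            ((kk + 8) % N_COLUMNS, kk) for kk in range(N_COLUMNS)
        ]
    for post, pre in cl2_to_cl1a_pairs:
        ff[post, 16 + pre] = True

    # 3. CL1a <-> CL1a where CBL arbors overlap (|delta column| <= 2)
    c = cbl_column(k)
    overlap = np.abs(c[:, None] - c[None, :]) <= 2
    ff[CL1A, CL1A] |= overlap

    # 4. CL2 <-> CL2 within a nodulus hemisphere group
    left = k < 8
    same_group = (left[:, None] == left[None, :])
    ff[CL2, CL2] |= same_group

    # 5. bias onto every columnar neuron
    ff[:, BIAS_INDEX] = True

    mod = ff.copy()
    mod[:, BIAS_INDEX] = False
    return ConnectivityMask(ff, mod)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class WeightSet:
    """Free parameters of the circuit on a connectivity mask.

    Dense matrices of shape (32, 33); entries off the mask are zero.
    ``g_s`` holds the unmodulated weights, ``g_mod_cw`` / ``g_mod_ccw``
    the modulatory weights of the clockwise / counterclockwise
    angular-velocity neuron.
    """

    mask: ConnectivityMask
    g_s: np.ndarray
    g_mod_cw: np.ndarray
    g_mod_ccw: np.ndarray

    def __post_init__(self) -> None:
        for name in ("g_s", "g_mod_cw", "g_mod_ccw"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (N_COLUMNAR, N_PRE):
                raise ValueError(f"{name} must have shape (32, 33)")
            setattr(self, name, m)
        if np.any(self.g_s[~self.mask.ff_mask] != 0.0):
            raise ValueError("g_s has nonzero entries off the mask")
        for name in ("g_mod_cw", "g_mod_ccw"):
            if np.any(getattr(self, name)[~self.mask.mod_mask] != 0.0):
                raise ValueError(f"{name} has nonzero entries off the mask")

    @classmethod
    def zeros(cls, mask: ConnectivityMask) -> "WeightSet":
        z = np.zeros((N_COLUMNAR, N_PRE))
        return cls(mask, z.copy(), z.copy(), z.copy())

    @classmethod
    def from_vector(cls, mask: ConnectivityMask, theta: np.ndarray) -> "WeightSet":
        """Unpack a flat parameter vector (g_s, g_mod_cw, g_mod_ccw)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (mask.n_free_parameters,):
            raise ValueError(
                f"expected {mask.n_free_parameters} parameters, got {theta.shape}"
            )
        n_ff, n_mod = mask.n_ff, mask.n_mod
        ws = cls.zeros(mask)
        ws.g_s[mask.ff_mask] = theta[:n_ff]
        ws.g_mod_cw[mask.mod_mask] = theta[n_ff : n_ff + n_mod]
        ws.g_mod_ccw[mask.mod_mask] = theta[n_ff + n_mod :]
        return ws

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.g_s[self.mask.ff_mask],
                self.g_mod_cw[self.mask.mod_mask],
                self.g_mod_ccw[self.mask.mod_mask],
            ]
        )

    def effective(self, p_rel_cw: float, p_rel_ccw: float) -> np.ndarray:
        """Effective (modulated) weight matrix at given release probabilities."""
        return self.g_s + p_rel_cw * self.g_mod_cw + p_rel_ccw * self.g_mod_ccw

    def perturbed(self, rng: np.random.Generator, rel_range: float) -> "WeightSet":
        """Multiplicative uniform weight noise in [1 - range, 1 + range]."""
        def jitter(m):
            return m * rng.uniform(1.0 - rel_range, 1.0 + rel_range, size=m.shape)

        return WeightSet(
            self.mask, jitter(self.g_s), jitter(self.g_mod_cw), jitter(self.g_mod_ccw)
        )

    def dynamics(self, constants: ModelConstants) -> CircuitDynamics:
        return CircuitDynamics(self.g_s, self.g_mod_cw, self.g_mod_ccw, constants)


# ---------------------------------------------------------------------------
# state, inputs, simulation
# ---------------------------------------------------------------------------

@dataclass
class CircuitState:
    """Instantaneous circuit state.

    ``rates`` holds 34 entries in Hz (16 CL1a, 16 CL2, AV_cw, AV_ccw);
    ``p_s`` the 33 presynaptic open probabilities (columnar + bias);
    ``p_rel`` the two modulatory release probabilities; ``phi_true`` the
    co-integrated ground-truth heading in degrees; ``t`` the time in ms.
    """

    rates: np.ndarray
    p_s: np.ndarray
    p_rel: np.ndarray
    phi_true: float
    t: float = 0.0

    @property
    def r_cl1a(self) -> np.ndarray:
        return self.rates[CL1A]

    @property
    def r_cl2(self) -> np.ndarray:
        return self.rates[CL2]


def av_rates(v, constants: ModelConstants = ModelConstants(), clip: bool = True):
    """Rates (Hz) of the clockwise / counterclockwise AV neurons for v (deg/s).

    Each neuron responds linearly to the speed of its preferred turning
    direction up to ``r_av_max`` at ``v_max``. Out-of-range speeds are
    clipped when ``clip`` is true and rejected otherwise.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(v) > constants.v_max):
        if not clip:
            raise ValueError(f"|v| exceeds v_max={constants.v_max} deg/s")
        v = np.clip(v, -constants.v_max, constants.v_max)
    scale = constants.r_av_max / constants.v_max
    r_cw = scale * np.abs(v) * (v > 0)
    r_ccw = scale * np.abs(v) * (v < 0)
    return r_cw, r_ccw


def encode_heading(phi_deg, constants: ModelConstants = ModelConstants()):
    """Sinusoidal population encoding of a heading: 16 rates (Hz)."""
    phi = np.asarray(phi_deg, dtype=float)
    ang = np.deg2rad(PHI_PREF_DEG - np.atleast_1d(phi)[..., None])
    return constants.bump_amplitude * np.cos(ang) + constants.bump_baseline


def init_state(
    phi0: float,
    constants: ModelConstants = ModelConstants(),
    rate_noise: Optional[np.ndarray] = None,
) -> CircuitState:
    """Stationary circuit state encoding heading ``phi0``.

    CL1a- and CL2-populations get identical sinusoidal rates; the
    angular-velocity neurons are silent (v = 0); every synapse sits at
    the fixed point of its presynaptic rate and both release
    probabilities are zero. ``rate_noise`` (32 entries, Hz) perturbs the
    presynaptic columnar rates before the synaptic fixed points are
    computed, as used by the attractor-stability protocol.
    """
    phi0 = float(wrap_deg(phi0))
    bump = encode_heading(phi0, constants)[0]
    rates = np.concatenate([bump, bump, [0.0, 0.0]])
    presyn = np.concatenate([rates[:N_COLUMNAR], [constants.r_bias]])
    if rate_noise is not None:
        presyn = presyn.copy()
        presyn[:N_COLUMNAR] = np.maximum(presyn[:N_COLUMNAR] + rate_noise, 0.0)
        rates = rates.copy()
        rates[:N_COLUMNAR] = presyn[:N_COLUMNAR]
    p_s = synapse_fixed_point(presyn, constants)
    return CircuitState(rates=rates, p_s=p_s, p_rel=np.zeros(2), phi_true=phi0)


@dataclass
class SimulationResult:
    """Trajectory of a forward simulation (interface units: ms, Hz, deg)."""

    t: np.ndarray             # (n+1,)
    rates: np.ndarray         # (n+1, 34)
    p_s: np.ndarray           # (n+1, 33)
    p_rel: np.ndarray         # (n+1, 2)
    phi_true: np.ndarray      # (n+1,)

    @property
    def r_cl1a(self) -> np.ndarray:
        return self.rates[:, CL1A]

    @property
    def r_cl2(self) -> np.ndarray:
        return self.rates[:, CL2]

    def decoded_heading(self) -> np.ndarray:
        return np.array([decode_heading(r) for r in self.r_cl1a])

    def final_state(self) -> CircuitState:
        return CircuitState(
            rates=self.rates[-1],
            p_s=self.p_s[-1],
            p_rel=self.p_rel[-1],
            phi_true=float(self.phi_true[-1]),
            t=float(self.t[-1]),
        )


def simulate(
    weights: WeightSet,
    av: np.ndarray,
    phi0: float,
    dt: float = 1.0,
    constants: ModelConstants = ModelConstants(),
    initial_state: Optional[CircuitState] = None,
) -> SimulationResult:
    """Forward-simulate the circuit under an angular-velocity time series.

    ``av`` gives the angular velocity in deg/s, one sample per
    integration step (zero-order hold within each step). The
    ground-truth heading is co-integrated alongside the circuit. Returns
    the full state trajectory including the initial state.
    """
    av = np.asarray(av, dtype=float)
    if av.ndim != 1:
        raise ValueError("av must be a 1-D series with one sample per step")
    n = av.size
    state0 = init_state(phi0, constants) if initial_state is None else initial_state
    engine = weights.dynamics(constants)

    ps = state0.p_s[None, :].copy()
    prel = state0.p_rel[None, :].copy()
    r_cw, r_ccw = av_rates(av, constants)
    m = np.stack([r_cw, r_ccw], axis=1) / constants.r_av_max

    rates = np.empty((n + 1, 34))
    ps_traj = np.empty((n + 1, N_PRE))
    prel_traj = np.empty((n + 1, 2))
    rates[0] = state0.rates
    ps_traj[0] = state0.p_s
    prel_traj[0] = state0.p_rel
    for i in range(n):
        ps, prel = engine.rk4_step(ps, prel, m[i : i + 1], dt)
        r_khz = engine.rates_khz(ps, prel)
        rates[i + 1, :N_COLUMNAR] = 1000.0 * r_khz[0]
        rates[i + 1, 32] = r_cw[i]
        rates[i + 1, 33] = r_ccw[i]
        ps_traj[i + 1] = ps[0]
        prel_traj[i + 1] = prel[0]

    t = np.arange(n + 1) * dt + state0.t
    phi_true = wrap_deg(
        state0.phi_true + np.concatenate([[0.0], np.cumsum(av) * dt / 1000.0])
    )
    return SimulationResult(t, rates, ps_traj, prel_traj, phi_true)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

_DESIGN = np.column_stack(
    [
        np.cos(np.deg2rad(PHI_PREF_DEG)),
        np.sin(np.deg2rad(PHI_PREF_DEG)),
        np.ones(N_COLUMNS),
    ]
)
_DESIGN_PINV = np.linalg.pinv(_DESIGN)


def cosine_fit(r_cl1a: np.ndarray):
    """Least-squares cosine fit to a 16-rate profile (possibly batched).

    Fits ``r ~ alpha cos(phi_pref) + beta sin(phi_pref) + gamma`` and
    returns ``(phase_deg, amplitude, residual_rms)``.
    """
    r = np.asarray(r_cl1a, dtype=float)
    coef = r @ _DESIGN_PINV.T
    alpha, beta, gamma = coef[..., 0], coef[..., 1], coef[..., 2]
    phase = wrap_deg(np.rad2deg(np.arctan2(beta, alpha)))
    amplitude = np.hypot(alpha, beta)
    resid = r - coef @ _DESIGN.T
    resid_rms = np.sqrt(np.mean(resid**2, axis=-1))
    return phase, amplitude, resid_rms


def decode_heading(
    r_cl1a: np.ndarray,
    amplitude_eps: float = 1e-8,
    return_amplitude: bool = False,
):
    """Heading (deg) encoded by 16 CL1a rates, via the best-fitting cosine.

    Raises :class:`~cxheading.exceptions.UndefinedPhaseError` when the
    fitted amplitude is below ``amplitude_eps`` (no bump to decode).
    """
    r = np.asarray(r_cl1a, dtype=float)
    if r.shape != (N_COLUMNS,):
        raise ValueError("decode_heading expects exactly 16 rates")
    if not np.all(np.isfinite(r)):
        raise ValueError("rates must be finite")
    phase, amplitude, _ = cosine_fit(r)
    if amplitude < amplitude_eps:
        raise UndefinedPhaseError(
            f"fitted amplitude {amplitude:.3g} below eps={amplitude_eps:g}"
        )
    if return_amplitude:
        return float(phase), float(amplitude)
    return float(phase)
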