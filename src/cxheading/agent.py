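"""Closed-loop walking agent: heading circuit + goal-directed steering.

The heading circuit's CL1a output is squashed through a logistic sigmoid
into a rounded square wave, mapped by an optimised non-negative 8 x 16
connection matrix onto TB1-neurons (the steering circuit's heading
layer), and compared column-wise against a fixed goal encoding held in
CPU4-neurons. CPU1-style left/right comparators turn the mismatch into
a signed steering command that drives the simulated walker; the
realised angular velocity (steering plus wind-induced rotation) is fed
back into the angular-velocity neurons of the heading circuit, closing
the loop.

The steering circuitry follows the published goal-directed steering
model for the insect central complex, adapted to the single-bump
16-column heading representation: the CL1a→TB1 map is re-derived by
constrained optimisation with a -5 degree phase shift compensating the
discrete-time interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import nnls
from scipy.special import expit

from .constants import ModelConstants
from .circuit import (
    N_COLUMNS,
    WeightSet,
    encode_heading,
    wrap_deg,
)
from .dynamics import synapse_fixed_point
from .evaluation import angular_error

__all__ = [
    "SteeringParams",
    "SteeringInterface",
    "WindConfig",
    "AgentState",
    "AgentTrialResult",
    "AgentSuiteResult",
    "build_cl1a_tb1_mask",
    "optimize_cl1a_tb1_map",
    "tb1_bump",
    "steering_step",
    "run_agent_trial",
    "run_agent_suite",
]

N_TB1 = 8
#: preferred direction of TB1 unit j, degrees
PSI_TB1_DEG = np.arange(N_TB1) * 45.0


@dataclass(frozen=True)
class SteeringParams:
    """Constants of the steering interface and motor loop.

    ``squash_offset`` / ``squash_slope`` (Hz) set the logistic sigmoid
    that turns CL1a rates into a rounded square wave in [0, 1];
    ``bump_sharpness`` shapes the rounded-square-wave target bumps;
    ``phase_shift_deg`` is the deliberate CL1a→TB1 phase offset;
    ``ridge`` the quadratic weight decay of the map fit; ``motor_gain``
    converts the steering signal into an angular velocity (deg/s);
    ``v_motor_max`` caps the commanded turn rate; ``step_length`` and
    ``step_duration_ms`` define the walker's constant forward gait.
    """

    squash_offset: float = 25.0
    squash_slope: float = 2.5
    bump_sharpness: float = 4.0
    phase_shift_deg: float = -5.0
    ridge: float = 0.1
    n_fit_phases: int = 128
    motor_gain: float = 150.0
    v_motor_max: float = 150.0
    goal_length: float = 1.0
    step_length: float = 1.0
    step_duration_ms: float = 100.0
    circuit_dt_ms: float = 1.0


@dataclass
class SteeringInterface:
    """Optimised non-negative CL1a→TB1 map plus squashing parameters."""

    weights: np.ndarray                # (8, 16), >= 0, zero off the mask
    mask: np.ndarray                   # (8, 16) bool
    params: SteeringParams = field(default_factory=SteeringParams)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_TB1, N_COLUMNS):
            raise ValueError("interface weights must have shape (8, 16)")
        if np.any(w < 0.0):
            raise ValueError("interface weights must be non-negative")
        if np.any(w[~np.asarray(self.mask, dtype=bool)] != 0.0):
            raise ValueError("interface weights must vanish off the mask")
        self.weights = w

    def squash(self, r_cl1a: np.ndarray) -> np.ndarray:
        """Logistic squashing of CL1a rates (Hz) to a rounded square wave."""
        p = self.params
        return expit((np.asarray(r_cl1a, dtype=float) - p.squash_offset) / p.squash_slope)

    def tb1_rates(self, r_cl1a: np.ndarray) -> np.ndarray:
        """TB1 activity (dimensionless, ~[0, 1]) for CL1a rates (..., 16)."""
        return self.squash(r_cl1a) @ self.weights.T


def build_cl1a_tb1_mask(half_width: int = 2) -> np.ndarray:
    """Permissible CL1a→TB1 synapses.

    Each TB1 subtype arborises in two PB domains eight columns apart;
    potential inputs are the CL1a-neurons within ``half_width`` columns
    of either domain (the liberal reading needed to realise the -5 deg
    phase shift).
    """
    mask = np.zeros((N_TB1, N_COLUMNS), dtype=bool)
    for j in range(N_TB1):
        for centre in (2 * j, 2 * j + 8):
            for off in range(-half_width, half_width + 1):
                mask[j, (centre + off) % N_COLUMNS] = True
    return mask


def tb1_bump(theta_deg, params: SteeringParams = SteeringParams()) -> np.ndarray:
    """Rounded-square-wave TB1 target bump centred on ``theta`` (degrees)."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    ang = np.deg2rad(PSI_TB1_DEG - theta[..., None])
    out = expit(params.bump_sharpness * np.cos(ang))
    return out[0] if np.isscalar(theta_deg) else out


def optimize_cl1a_tb1_map(
    seed: int = 0,
    params: SteeringParams = SteeringParams(),
    constants: ModelConstants = ModelConstants(),
    mask: Optional[np.ndarray] = None,
) -> SteeringInterface:
    """Fit the non-negative CL1a→TB1 map by ridge-regularised NNLS.

    Squashed sinusoidal CL1a bumps at ``n_fit_phases`` evenly spaced
    headings (jittered by the seed) are mapped onto TB1 rounded square
    waves shifted by ``phase_shift_deg``; a quadratic weight decay
    prunes unnecessary connections toward zero.
    """
    if mask is None:
        mask = build_cl1a_tb1_mask()
    rng = np.random.default_rng(seed)
    phases = (
        np.linspace(0.0, 360.0, params.n_fit_phases, endpoint=False)
        + rng.uniform(0.0, 360.0 / params.n_fit_phases)
    )
    x = expit(
        (encode_heading(phases, constants) - params.squash_offset)
        / params.squash_slope
    )                                                     # (P, 16)
    t = tb1_bump(phases + params.phase_shift_deg, params)  # (P, 8)

    w = np.zeros((N_TB1, N_COLUMNS))
    sqrt_ridge = np.sqrt(params.ridge)
    for j in range(N_TB1):
        cols = np.flatnonzero(mask[j])
        a = np.vstack([x[:, cols], sqrt_ridge * np.eye(cols.size)])
        b = np.concatenate([t[:, j], np.zeros(cols.size)])
        w[j, cols], _ = nnls(a, b)
    return SteeringInterface(w, mask, params)


# ---------------------------------------------------------------------------
# steering comparator
# ---------------------------------------------------------------------------

def goal_encoding(goal_deg, params: SteeringParams = SteeringParams()) -> np.ndarray:
    """Fixed CPU4 goal representation: rounded square wave at the goal."""
    return params.goal_length * tb1_bump(goal_deg, params)


def steering_step(
    tb1: np.ndarray,
    goal: np.ndarray,
    params: SteeringParams = SteeringParams(),
) -> np.ndarray:
    """Signed turn command (deg/s) from TB1 activity and the goal encoding.

    CPU1-style comparators subtract the TB1 heading bump, shifted one
    column left or right, from the CPU4 goal encoding; the rectified
    column sums of the two comparator populations are differenced and
    scaled by the motor gain. Positive output commands a clockwise turn
    (increasing heading angle); the command is an odd function of the
    heading error and vanishes when heading and goal align.
    """
    tb1 = np.asarray(tb1, dtype=float)
    goal = np.asarray(goal, dtype=float)
    right = np.maximum(goal - np.roll(tb1, -1, axis=-1), 0.0).sum(axis=-1)
    left = np.maximum(goal - np.roll(tb1, 1, axis=-1), 0.0).sum(axis=-1)
    cmd = params.motor_gain * (right - left)
    return np.clip(cmd, -params.v_motor_max, params.v_motor_max)


# ---------------------------------------------------------------------------
# wind and agent state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindConfig:
    """Gust probabilities per agent step and the gust-duration range (ms).

    Translation gusts displace the agent laterally by one step length
    per step without touching its heading; rotation gusts rotate it by
    a random total magnitude spread smoothly over the gust. The two are
    mutually exclusive, so the probabilities must sum to at most one.
    """

    p_translation: float = 0.0
    p_rotation: float = 0.0
    gust_duration_ms: Tuple[float, float] = (500.0, 1500.0)
    rotation_magnitude_deg: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_translation <= 1.0 and 0.0 <= self.p_rotation <= 1.0):
            raise ValueError("gust probabilities must lie in [0, 1]")
        if self.p_translation + self.p_rotation > 1.0:
            raise ValueError(
                "translation and rotation are mutually exclusive: "
                "p_translation + p_rotation must be <= 1"
            )
        lo, hi = self.gust_duration_ms
        if not 0.0 < lo <= hi:
            raise ValueError("gust duration range must be positive and ordered")


@dataclass
class AgentState:
    """Pose of the simulated walker (step-length units, degrees)."""

    position: np.ndarray
    heading: float
    speed: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = float(wrap_deg(self.heading))


@dataclass
class AgentTrialResult:
    """One closed-loop trial: trajectory and goal-holding metrics."""

    t_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray
    goal_deg: float
    wind_state: np.ndarray          # 0 none, 1 translation, 2 rotation
    final_deviation_deg: float
    final_signed_deviation_deg: float


@dataclass
class AgentSuiteResult:
    """Aggregate of many agent trials under one wind condition."""

    final_deviation: np.ndarray          # (n,), absolute, degrees
    signed_deviation: np.ndarray         # (n,), degrees in (-180, 180]
    checkpoint_t_s: np.ndarray           # (k,)
    checkpoint_mean_abs: np.ndarray      # (k,) mean |deviation| at checkpoints
    wind: WindConfig
    n_trials: int

    @property
    def median_final(self) -> float:
        return float(np.median(self.final_deviation))


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

def _signed_error(phi, goal):
    """Signed angular deviation heading - goal, in (-180, 180]."""
    return -(np.mod(goal - phi + 180.0, 360.0) - 180.0)


def run_agent_suite(
    weights: WeightSet,
    interface: SteeringInterface,
    wind: WindConfig = WindConfig(),
    n_trials: int = 2000,
    n_steps: int = 200,
    seed: int = 0,
    constants: ModelConstants = ModelConstants(),
    checkpoint_every_s: float = 5.0,
) -> AgentSuiteResult:
    """Closed-loop goal holding for a batch of agents (vectorised trials).

    Each agent starts at the origin with a random heading and a random
    fixed goal direction, then walks ``n_steps`` steps of 0.1 s. Within
    each step the heading circuit is integrated in 1 ms increments
    under the realised angular velocity (steering command plus
    wind-induced rotation), and the commanded turn is recomputed from
    the circuit's CL1a activity once per step.
    """
    p = interface.params
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 360.0, n_trials)
    goal = rng.uniform(0.0, 360.0, n_trials)
    goal_enc = goal_encoding(goal, p)                    # (B, 8)

    bump = encode_heading(phi0, constants)
    presyn = np.concatenate([bump, bump, np.full((n_trials, 1), constants.r_bias)], axis=1)
    ps = synapse_fixed_point(presyn, constants)
    prel = np.zeros((n_trials, 2))
    engine = weights.dynamics(constants)

    heading = phi0.copy()
    pos = np.zeros((n_trials, 2))
    substeps = int(round(p.step_duration_ms / p.circuit_dt_ms))
    dt_s = p.circuit_dt_ms / 1000.0

    # wind bookkeeping (per trial)
    gust_left = np.zeros(n_trials, dtype=int)           # remaining steps
    gust_kind = np.zeros(n_trials, dtype=int)           # 0/1/2
    gust_rate = np.zeros(n_trials)                      # deg/s while rotating

    # checkpoint at t = 0 records the random-initialisation deviation, so
    # the checkpoint series shows the alignment transient as well as any
    # late drift accumulation
    checkpoints = [(0.0, float(np.mean(angular_error(heading, goal))))]
    check_stride = max(1, int(round(1000.0 * checkpoint_every_s / p.step_duration_ms)))

    for step in range(n_steps):
        # start new gusts where none is active
        idle = gust_left == 0
        u = rng.uniform(size=n_trials)
        start_t = idle & (u < wind.p_translation)
        start_r = idle & ~start_t & (u < wind.p_translation + wind.p_rotation)
        n_new = int(start_t.sum() + start_r.sum())
        if n_new:
            dur_ms = rng.uniform(*wind.gust_duration_ms, size=n_trials)
            steps_new = np.maximum(1, np.round(dur_ms / p.step_duration_ms)).astype(int)
            total_rot = rng.uniform(
                -wind.rotation_magnitude_deg, wind.rotation_magnitude_deg, n_trials
            )
            for sel, kind in ((start_t, 1), (start_r, 2)):
                gust_left[sel] = steps_new[sel]
                gust_kind[sel] = kind
            gust_rate[start_r] = total_rot[start_r] / (
                gust_left[start_r] * p.step_duration_ms / 1000.0
            )
            gust_rate[start_t] = 0.0

        # steering command from the circuit's current heading representation
        r_cl1a = 1000.0 * engine.rates_khz(ps, prel)[:, :16]
        tb1 = interface.tb1_rates(r_cl1a)
        v_cmd = steering_step(tb1, goal_enc, p)

        rotating = gust_kind == 2
        translating = gust_kind == 1
        v_real = v_cmd + np.where(rotating & (gust_left > 0), gust_rate, 0.0)

        # integrate circuit and true heading through the agent step
        m = np.zeros((n_trials, 2))
        v_clipped = np.clip(v_real, -constants.v_max, constants.v_max)
        m[:, 0] = np.where(v_clipped > 0, v_clipped, 0.0) / constants.v_max
        m[:, 1] = np.where(v_clipped < 0, -v_clipped, 0.0) / constants.v_max
        for _ in range(substeps):
            ps, prel = engine.rk4_step(ps, prel, m, p.circuit_dt_ms)
        heading = wrap_deg(heading + v_real * (p.step_duration_ms / 1000.0))

        # forward gait (no side-stepping, no turning on the spot) plus
        # lateral displacement while a translation gust is active
        hr = np.deg2rad(heading)
        fwd = np.stack([np.cos(hr), np.sin(hr)], axis=1)
        lateral = np.stack([np.sin(hr), -np.cos(hr)], axis=1)
        pos += p.step_length * fwd
        pos += p.step_length * lateral * (translating & (gust_left > 0))[:, None]

        gust_left = np.maximum(gust_left - 1, 0)
        gust_kind[gust_left == 0] = 0

        if (step + 1) % check_stride == 0:
            checkpoints.append(
                (
                    (step + 1) * p.step_duration_ms / 1000.0,
                    float(np.mean(angular_error(heading, goal))),
                )
            )

    signed = _signed_error(heading, goal)
    t_chk = np.array([c[0] for c in checkpoints])
    m_chk = np.array([c[1] for c in checkpoints])
    return AgentSuiteResult(
        final_deviation=np.abs(signed),
        signed_deviation=signed,
        checkpoint_t_s=t_chk,
        checkpoint_mean_abs=m_chk,
        wind=wind,
        n_trials=n_trials,
    )


def run_agent_trial(
    weights: WeightSet,
    interface: SteeringInterface,
    wind: WindConfig = WindConfig(),
    seed: int = 0,
    n_steps: int = 200,
    constants: ModelConstants = ModelConstants(),
    phi0: Optional[float] = None,
    goal: Optional[float] = None,
) -> AgentTrialResult:
    """Single closed-loop trial with a full recorded trajectory."""
    p = interface.params
    rng = np.random.default_rng(seed)
    phi = float(rng.uniform(0.0, 360.0)) if phi0 is None else float(phi0)
    goal_dir = float(rng.uniform(0.0, 360.0)) if goal is None else float(goal)
    goal_enc = goal_encoding(np.array([goal_dir]), p)

    bump = encode_heading(phi, constants)[0]
    presyn = np.concatenate([bump, bump, [constants.r_bias]])
    ps = synapse_fixed_point(presyn, constants)[None, :]
    prel = np.zeros((1, 2))
    engine = weights.dynamics(constants)

    heading = phi
    pos = np.zeros(2)
    substeps = int(round(p.step_duration_ms / p.circuit_dt_ms))
    gust_left, gust_kind, gust_rate = 0, 0, 0.0

    t_s = [0.0]
    xs, ys, hs, winds = [0.0], [0.0], [heading], [0]
    for step in range(n_steps):
        if gust_left == 0:
            u = rng.uniform()
            if u < wind.p_translation:
                gust_kind = 1
            elif u < wind.p_translation + wind.p_rotation:
                gust_kind = 2
            if gust_kind:
                dur = rng.uniform(*wind.gust_duration_ms)
                gust_left = max(1, int(round(dur / p.step_duration_ms)))
                if gust_kind == 2:
                    total = rng.uniform(
                        -wind.rotation_magnitude_deg, wind.rotation_magnitude_deg
                    )
                    gust_rate = total / (gust_left * p.step_duration_ms / 1000.0)

        r_cl1a = 1000.0 * engine.rates_khz(ps, prel)[0, :16]
        tb1 = interface.tb1_rates(r_cl1a)
        v_cmd = float(steering_step(tb1, goal_enc[0], p))
        v_real = v_cmd + (gust_rate if gust_kind == 2 and gust_left > 0 else 0.0)

        v_clip = np.clip(v_real, -constants.v_max, constants.v_max)
        m = np.array([[max(v_clip, 0.0), max(-v_clip, 0.0)]]) / constants.v_max
        for _ in range(substeps):
            ps, prel = engine.rk4_step(ps, prel, m, p.circuit_dt_ms)
        heading = float(wrap_deg(heading + v_real * p.step_duration_ms / 1000.0))

        hr = np.deg2rad(heading)
        pos = pos + p.step_length * np.array([np.cos(hr), np.sin(hr)])
        if gust_kind == 1 and gust_left > 0:
            pos = pos + p.step_length * np.array([np.sin(hr), -np.cos(hr)])

        winds.append(gust_kind if gust_left > 0 else 0)
        gust_left = max(gust_left - 1, 0)
        if gust_left == 0:
            gust_kind, gust_rate = 0, 0.0

        t_s.append((step + 1) * p.step_duration_ms / 1000.0)
        xs.append(float(pos[0]))
        ys.append(float(pos[1]))
        hs.append(heading)

    signed = float(_signed_error(heading, goal_dir))
    return AgentTrialResult(
        t_s=np.array(t_s),
        x=np.array(xs),
        y=np.array(ys),
        heading_deg=np.array(hs),
        goal_deg=goal_dir,
        wind_state=np.array(winds),
        final_deviation_deg=abs(signed),
        final_signed_deviation_deg=signed,
    )
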