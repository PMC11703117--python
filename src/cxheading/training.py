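"""Weight optimisation: targets, objective, analytic gradient, L-BFGS fit.

The free parameters (all masked feed-forward and modulatory weights) are
fitted so that, starting from a sinusoidal heading encoding, the circuit
(i) holds the encoding in place when the angular velocity is zero and
(ii) moves it to the correct new heading after integrating a constant
angular velocity for the first four fifths of a 200 ms horizon.

The objective is the sum of four mean-squared-error terms (CL1a and CL2
rates against maintenance targets at every 10th integration step, and
against shift targets over the final 10 steps) plus a diagonal-variance
regulariser that favours rotation-equivariant weight patterns along the
wrapped diagonals of the four 16 x 16 quadrants of the connectivity
matrix.

Gradients are computed by reverse-mode (adjoint) differentiation through
the RK4 integration, implemented here directly on top of the vectorised
drift of :class:`~cxheading.dynamics.CircuitDynamics`; the result is
exact to floating point and is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .constants import ModelConstants
from .circuit import (
    N_COLUMNS,
    N_COLUMNAR,
    N_PRE,
    ConnectivityMask,
    WeightSet,
    encode_heading,
    wrap_deg,
)
from .dynamics import CircuitDynamics, synapse_fixed_point
from .exceptions import DegenerateCircuitError

__all__ = [
    "TrainingConfig",
    "TrainingBatch",
    "TrainingReport",
    "true_heading",
    "make_targets",
    "make_training_batch",
    "loss",
    "loss_and_grad",
    "optimize",
]


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

def true_heading(av: np.ndarray, phi0: float, dt: float) -> np.ndarray:
    """Ground-truth heading (deg) from an angular-velocity node series.

    ``av`` holds samples (deg/s) on a regular grid with spacing ``dt``
    (ms); the integral is accumulated trapezoidally and wrapped to
    [0, 360). The returned series has the same length as ``av`` and
    starts at ``phi0``.
    """
    av = np.asarray(av, dtype=float)
    inc = np.concatenate([[0.0], np.cumsum(0.5 * (av[1:] + av[:-1])) * dt / 1000.0])
    return wrap_deg(phi0 + inc)


def make_targets(phi_deg, constants: ModelConstants = ModelConstants()) -> np.ndarray:
    """Target rate vector(s): the sinusoidal encoding of ``phi`` (16 Hz values).

    CL1a- and CL2-populations share identical targets, so one 16-vector
    per heading serves both.
    """
    return encode_heading(phi_deg, constants)


# ---------------------------------------------------------------------------
# batch and config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the weight fit (defaults are the study conditions)."""

    n_shift: int = 64
    n_maintenance: int = 64
    horizon_ms: float = 200.0
    dt: float = 4.0
    sample_stride: int = 10
    final_window: int = 10
    reg_weight: float = 0.1
    init_scale: float = 0.01
    max_iter: int = 3000
    history_size: int = 50
    gtol: float = 1e-7
    modulated_population: str = "both"


@dataclass
class TrainingBatch:
    """One batch of maintenance and shift trials.

    ``v_shift`` holds the constant angular velocity (deg/s) applied
    during the first four fifths of the horizon of each shift trial;
    maintenance trials have zero velocity throughout.
    """

    phi0_maintenance: np.ndarray
    phi0_shift: np.ndarray
    v_shift: np.ndarray
    horizon_ms: float = 200.0
    dt: float = 4.0

    def __post_init__(self) -> None:
        if np.any(np.abs(self.v_shift) > 150.0 + 1e-9):
            raise ValueError("shift velocities must lie in [-150, 150] deg/s")
        n_steps = self.horizon_ms / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("horizon must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_ms / self.dt))

    @property
    def shift_steps(self) -> int:
        """Number of steps with nonzero velocity (first 4/5 of the horizon)."""
        return (4 * self.n_steps) // 5

    def shift_target_heading(self) -> np.ndarray:
        """Heading after integrating the constant velocity over the shift phase."""
        t_shift_s = self.shift_steps * self.dt / 1000.0
        return wrap_deg(self.phi0_shift + self.v_shift * t_shift_s)


def make_training_batch(
    seed_or_rng,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingBatch:
    """Draw a training batch: uniform random headings, uniform velocities."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return TrainingBatch(
        phi0_maintenance=rng.uniform(0.0, 360.0, size=config.n_maintenance),
        phi0_shift=rng.uniform(0.0, 360.0, size=config.n_shift),
        v_shift=rng.uniform(-150.0, 150.0, size=config.n_shift),
        horizon_ms=config.horizon_ms,
        dt=config.dt,
    )


# ---------------------------------------------------------------------------
# diagonal-variance regulariser
# ---------------------------------------------------------------------------

def _theta_index_maps(mask: ConnectivityMask) -> List[np.ndarray]:
    """Per-class (32, 33) maps from matrix position to flat theta index (-1 off)."""
    maps = []
    offset = 0
    for m in (mask.ff_mask, mask.mod_mask, mask.mod_mask):
        idx = -np.ones((N_COLUMNAR, N_PRE), dtype=int)
        idx[m] = offset + np.arange(int(m.sum()))
        offset += int(m.sum())
        maps.append(idx)
    return maps


def _diagonal_groups(mask: ConnectivityMask) -> List[np.ndarray]:
    """Theta-index groups: masked entries on each wrapped quadrant diagonal.

    The four quadrants are the 16 x 16 blocks CL1a->CL1a, CL2->CL1a,
    CL1a->CL2 and CL2->CL2 of the columnar weight matrix (the bias
    column belongs to no quadrant). Diagonal ``d`` of a quadrant is the
    set of entries (row, (row + d) mod 16); groups with fewer than two
    masked entries carry no variance and are dropped. The same grouping
    applies to all three weight classes.
    """
    groups: List[np.ndarray] = []
    for idx_map in _theta_index_maps(mask):
        for rb in (0, 16):
            for cb in (0, 16):
                block = idx_map[rb : rb + 16, cb : cb + 16]
                for d in range(N_COLUMNS):
                    rows = np.arange(N_COLUMNS)
                    vals = block[rows, (rows + d) % N_COLUMNS]
                    vals = vals[vals >= 0]
                    if vals.size >= 2:
                        groups.append(vals)
    return groups


def _regulariser(theta: np.ndarray, groups: List[np.ndarray]) -> Tuple[float, np.ndarray]:
    """Sum of per-diagonal variances and its gradient."""
    reg = 0.0
    grad = np.zeros_like(theta)
    for g in groups:
        w = theta[g]
        mu = w.mean()
        dev = w - mu
        reg += float(np.mean(dev**2))
        grad[g] += 2.0 * dev / w.size
    return reg, grad


# ---------------------------------------------------------------------------
# objective and adjoint gradient
# ---------------------------------------------------------------------------

class _Objective:
    """Evaluates the training loss and its gradient for a fixed batch.

    All trials (maintenance first, then shift) are simulated as one
    vectorised batch; states are recorded as ``R[j]`` = rates after
    ``j`` integration steps for ``j = 0..n_steps - 1``, matching the
    every-10th-step / final-10-step sampling windows.
    """

    def __init__(
        self,
        mask: ConnectivityMask,
        batch: TrainingBatch,
        constants: ModelConstants = ModelConstants(),
        reg_weight: float = 0.1,
        sample_stride: int = 10,
        final_window: int = 10,
    ) -> None:
        self.mask = mask
        self.batch = batch
        self.c = constants
        self.reg_weight = reg_weight
        self.groups = _diagonal_groups(mask)

        n_m = batch.phi0_maintenance.size
        n_s = batch.phi0_shift.size
        self.n_m, self.n_s = n_m, n_s
        b = n_m + n_s
        self.n_states = batch.n_steps          # states 0 .. n_steps-1
        self.maint_rows = np.arange(n_m)
        self.shift_rows = np.arange(n_m, b)
        self.maint_steps = np.arange(0, self.n_states, sample_stride)
        self.shift_steps_idx = np.arange(self.n_states - final_window, self.n_states)

        # initial synaptic state: fixed points of the initial encoding
        phi0 = np.concatenate([batch.phi0_maintenance, batch.phi0_shift])
        bump = encode_heading(phi0, constants)            # (B, 16) Hz
        presyn = np.concatenate(
            [bump, bump, np.full((b, 1), constants.r_bias)], axis=1
        )
        self.ps0 = synapse_fixed_point(presyn, constants)  # (B, 33)
        self.prel0 = np.zeros((b, 2))

        # normalised angular-velocity drive per step, (n_steps-1, B, 2)
        v = batch.v_shift
        m_shift = np.zeros((n_s, 2))
        m_shift[:, 0] = np.where(v > 0, np.abs(v), 0.0) / constants.v_max
        m_shift[:, 1] = np.where(v < 0, np.abs(v), 0.0) / constants.v_max
        n_trans = self.n_states - 1
        self.m_series = np.zeros((n_trans, b, 2))
        active = min(batch.shift_steps, n_trans)
        self.m_series[:active, n_m:, :] = m_shift[None, :, :]

        # targets, Hz
        self.target_m = bump[:n_m]                                # (n_m, 16)
        self.target_s = encode_heading(batch.shift_target_heading(), constants)

    # -- forward -----------------------------------------------------------

    def _forward(self, engine: CircuitDynamics, keep: bool):
        dt = self.batch.dt
        half = 0.5 * dt
        ps = self.ps0.copy()
        prel = self.prel0.copy()
        states = [(ps, prel)]
        stage_caches = [] if keep else None
        for n in range(self.n_states - 1):
            m = self.m_series[n]
            k1p, k1c, c1 = engine.drift(ps, prel, m, want_cache=True)
            z2p, z2c = ps + half * k1p, prel + half * k1c
            k2p, k2c, c2 = engine.drift(z2p, z2c, m, want_cache=True)
            z3p, z3c = ps + half * k2p, prel + half * k2c
            k3p, k3c, c3 = engine.drift(z3p, z3c, m, want_cache=True)
            z4p, z4c = ps + dt * k3p, prel + dt * k3c
            k4p, k4c, c4 = engine.drift(z4p, z4c, m, want_cache=True)
            ps = ps + (dt / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
            prel = prel + (dt / 6.0) * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
            states.append((ps, prel))
            if keep:
                stage_caches.append((c1, c2, c3, c4))
        return states, stage_caches

    def _rate_errors(self, engine: CircuitDynamics, states, want_caches: bool):
        """Loss terms and (optionally) per-sampled-state read-out caches."""
        data = 0.0
        readouts = {}
        cl1a, cl2 = slice(0, 16), slice(16, 32)
        for j in sorted(set(self.maint_steps) | set(self.shift_steps_idx)):
            ps, prel = states[j]
            r_khz, cache = engine.rates_khz(ps, prel, want_cache=True)
            r_hz = 1000.0 * r_khz
            g_r = np.zeros_like(r_hz)
            if j in self.maint_steps:
                err1 = r_hz[self.maint_rows, cl1a] - self.target_m
                err2 = r_hz[self.maint_rows, cl2] - self.target_m
                n1 = err1.size * self.maint_steps.size
                data += float((err1**2).sum() / n1 + (err2**2).sum() / n1)
                g_r[self.maint_rows, cl1a] += 2.0 * err1 / n1
                g_r[self.maint_rows, cl2] += 2.0 * err2 / n1
            if j in self.shift_steps_idx:
                err1 = r_hz[self.shift_rows, cl1a] - self.target_s
                err2 = r_hz[self.shift_rows, cl2] - self.target_s
                n1 = err1.size * self.shift_steps_idx.size
                data += float((err1**2).sum() / n1 + (err2**2).sum() / n1)
                g_r[self.shift_rows, cl1a] += 2.0 * err1 / n1
                g_r[self.shift_rows, cl2] += 2.0 * err2 / n1
            if want_caches:
                readouts[j] = (cache, 1000.0 * g_r)   # cotangent in kHz units
        return data, readouts

    # -- public ------------------------------------------------------------

    #: objective value returned for weight configurations that drive the
    #: steady-state denominator into degeneracy; the line search treats
    #: the region as an impassable wall and backtracks
    DEGENERATE_PENALTY = 1e12

    def value(self, theta: np.ndarray) -> Tuple[float, float, float]:
        """Return (total, data term, regulariser term)."""
        ws = WeightSet.from_vector(self.mask, theta)
        engine = ws.dynamics(self.c)
        try:
            states, _ = self._forward(engine, keep=False)
            data, _ = self._rate_errors(engine, states, want_caches=False)
        except DegenerateCircuitError:
            return self.DEGENERATE_PENALTY, self.DEGENERATE_PENALTY, 0.0
        reg, _ = _regulariser(theta, self.groups)
        return data + self.reg_weight * reg, data, reg

    def value_and_grad(self, theta: np.ndarray) -> Tuple[float, np.ndarray]:
        ws = WeightSet.from_vector(self.mask, theta)
        engine = ws.dynamics(self.c)
        try:
            states, stage_caches = self._forward(engine, keep=True)
            data, readouts = self._rate_errors(engine, states, want_caches=True)
        except DegenerateCircuitError:
            return self.DEGENERATE_PENALTY, np.zeros_like(theta)

        grad_gs = np.zeros((N_COLUMNAR, N_PRE))
        grad_gcw = np.zeros((N_COLUMNAR, N_PRE))
        grad_gccw = np.zeros((N_COLUMNAR, N_PRE))

        def accumulate(cache, g_s_cot):
            np.add(grad_gs, g_s_cot.T @ cache.ps_used, out=grad_gs)
            np.add(
                grad_gcw, (cache.c_cw[:, None] * g_s_cot).T @ cache.ps_used, out=grad_gcw
            )
            np.add(
                grad_gccw,
                (cache.c_ccw[:, None] * g_s_cot).T @ cache.ps_used,
                out=grad_gccw,
            )

        dt = self.batch.dt
        half = 0.5 * dt
        a = np.zeros_like(self.ps0)           # adjoint of P_s at current state
        for j in range(self.n_states - 1, -1, -1):
            if j in readouts:
                cache, g_r = readouts[j]
                a_ps, g_s_cot = engine.rates_vjp(cache, g_r)
                a += a_ps
                accumulate(cache, g_s_cot)
            if j == 0:
                break
            c1, c2, c3, c4 = stage_caches[j - 1]
            # reverse of one RK4 step: y' = y + dt/6 (k1 + 2k2 + 2k3 + k4)
            g_k4 = (dt / 6.0) * a
            a4, s4 = engine.drift_vjp(c4, g_k4)
            accumulate(c4, s4)
            g_k3 = (dt / 3.0) * a + dt * a4
            a3, s3 = engine.drift_vjp(c3, g_k3)
            accumulate(c3, s3)
            g_k2 = (dt / 3.0) * a + half * a3
            a2, s2 = engine.drift_vjp(c2, g_k2)
            accumulate(c2, s2)
            g_k1 = (dt / 6.0) * a + half * a2
            a1, s1 = engine.drift_vjp(c1, g_k1)
            accumulate(c1, s1)
            a = a + a1 + a2 + a3 + a4

        reg, reg_grad = _regulariser(theta, self.groups)
        grad = np.concatenate(
            [
                grad_gs[self.mask.ff_mask],
                grad_gcw[self.mask.mod_mask],
                grad_gccw[self.mask.mod_mask],
            ]
        )
        grad += self.reg_weight * reg_grad
        total = data + self.reg_weight * reg
        self.last_terms = (total, data, reg)   # read by the training logger
        return total, grad


def loss(
    weights: WeightSet,
    batch: TrainingBatch,
    constants: ModelConstants = ModelConstants(),
    reg_weight: float = 0.1,
) -> float:
    """Training objective for a weight set on a batch (data + regulariser)."""
    obj = _Objective(weights.mask, batch, constants, reg_weight)
    return obj.value(weights.to_vector())[0]


def loss_and_grad(
    weights: WeightSet,
    batch: TrainingBatch,
    constants: ModelConstants = ModelConstants(),
    reg_weight: float = 0.1,
) -> Tuple[float, np.ndarray]:
    """Objective and its analytic gradient with respect to the flat weights."""
    obj = _Objective(weights.mask, batch, constants, reg_weight)
    return obj.value_and_grad(weights.to_vector())


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

@dataclass
class TrainingReport:
    """Log of one optimisation run."""

    iterations: List[int] = field(default_factory=list)
    loss: List[float] = field(default_factory=list)
    data_term: List[float] = field(default_factory=list)
    reg_term: List[float] = field(default_factory=list)
    converged: bool = False
    message: str = ""
    final_loss: float = float("nan")
    wall_time_s: float = float("nan")

    def as_rows(self):
        return list(zip(self.iterations, self.loss, self.data_term, self.reg_term))


def optimize(
    mask: ConnectivityMask,
    seed: int,
    config: TrainingConfig = TrainingConfig(),
    constants: ModelConstants = ModelConstants(),
    batch: Optional[TrainingBatch] = None,
) -> Tuple[WeightSet, TrainingReport]:
    """Fit all free weights with L-BFGS on the maintenance + shift objective.

    The seed controls both the batch draw and the small uniform weight
    initialisation, so repeated calls are bit-reproducible. Issues a
    warning (in the report message) when the iteration budget runs out
    before the gradient tolerance is met.
    """
    rng = np.random.default_rng(seed)
    mask = mask.restrict_modulation(config.modulated_population)
    if batch is None:
        batch = make_training_batch(rng, config)
    obj = _Objective(
        mask,
        batch,
        constants,
        reg_weight=config.reg_weight,
        sample_stride=config.sample_stride,
        final_window=config.final_window,
    )
    theta0 = rng.uniform(-config.init_scale, config.init_scale, mask.n_free_parameters)

    report = TrainingReport()
    t0 = time.perf_counter()

    def record(theta):
        # last_terms comes from the most recent value_and_grad call, which
        # L-BFGS evaluates at (or very near) the accepted iterate
        total, data, reg = getattr(obj, "last_terms", (np.nan, np.nan, np.nan))
        report.iterations.append(len(report.iterations))
        report.loss.append(total)
        report.data_term.append(data)
        report.reg_term.append(reg)

    result = minimize(
        obj.value_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={
            "maxiter": config.max_iter,
            "maxcor": config.history_size,
            "gtol": config.gtol,
            "ftol": 1e-14,
        },
    )
    report.wall_time_s = time.perf_counter() - t0
    report.converged = bool(result.success)
    report.message = str(result.message)
    report.final_loss = float(result.fun)
    if not result.success:
        import warnings

        warnings.warn(
            f"L-BFGS stopped without convergence: {result.message} "
            f"(final loss {result.fun:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return WeightSet.from_vector(mask, result.x), report
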