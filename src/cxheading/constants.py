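"""Fixed physiological parameters of the heading-circuit model.

All quantities are kept in the units used throughout the package: time in
milliseconds, membrane potential in millivolts relative to rest, firing
rates in hertz at every public interface (the integration core converts to
spikes per millisecond internally), angles in degrees wrapped to
[0, 360).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass
from typing import Union

import yaml

__all__ = ["ModelConstants", "load_constants", "save_constants"]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the neuron, synapse and circuit model.

    Parameters
    ----------
    tau_m:
        Membrane time constant in ms. The model assumes steady-state
        firing-rate neurons, so ``tau_m`` never enters the integrated
        equations; it is retained to document and validate the
        slow-synapse assumption ``tau_s >> tau_m``.
    tau_s:
        Synaptic time constant in ms governing the decay of the
        post-synaptic channel open probability.
    tau_s_mod:
        Time constant in ms of the modulatory (pre-synaptic release
        probability) dynamics. Neuromodulation involves transmission
        cascades, hence ``tau_s_mod > tau_s``.
    r_max, slope, half_point:
        Coefficients of the logistic rate function
        ``r(U) = r_max / (1 + exp(-slope * (U - half_point)))``.
    P_s_max:
        Maximum synaptic open probability; fixed at 1.
    E_ex:
        Synaptic reversal potential (mV above rest) used for every
        synapse. The sign of a synaptic weight decides excitation versus
        inhibition, so a single reversal potential suffices; negative
        conductances are an abstraction of inhibitory pathways.
    E_in:
        Reversal potential of an explicit inhibitory pathway. Unused by
        the default signed-conductance abstraction; kept so that paired
        excitatory/inhibitory variants can be configured.
    r_bias:
        Constant rate (Hz) of the bias neuron that keeps every columnar
        neuron near its operating point.
    r_av_max:
        Maximum rate (Hz) of the two angular-velocity neurons.
    v_max:
        Maximum angular speed (deg/s) represented by the angular-velocity
        neurons.
    bump_amplitude, bump_baseline:
        Amplitude ``a`` and operating point ``b`` (Hz) of the sinusoidal
        heading encoding across the 16 columnar neurons of each
        population.
    dt:
        Default integration step in ms.
    """

    tau_m: float = 1.5
    tau_s: float = 20.0
    tau_s_mod: float = 40.0
    r_max: float = 99.6
    slope: float = 0.19
    half_point: float = 17.8
    P_s_max: float = 1.0
    E_ex: float = 60.0
    E_in: float = -60.0
    r_bias: float = 100.0
    r_av_max: float = 30.0
    v_max: float = 150.0
    bump_amplitude: float = 5.0
    bump_baseline: float = 25.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_s >= 10.0 * self.tau_m:
            raise ValueError(
                f"slow-synapse assumption violated: tau_s={self.tau_s} < "
                f"10 * tau_m={10 * self.tau_m}"
            )
        if not self.tau_s_mod > self.tau_s:
            raise ValueError(
                f"modulatory synapses must be slower: tau_s_mod="
                f"{self.tau_s_mod} <= tau_s={self.tau_s}"
            )
        if self.P_s_max != 1.0:
            raise ValueError("P_s_max is fixed at 1")
        if not (self.r_max > 0 and self.slope > 0):
            raise ValueError("r_max and slope must be positive")
        if not (self.r_av_max > 0 and self.v_max > 0):
            raise ValueError("r_av_max and v_max must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def save_constants(constants: ModelConstants, path: Union[str, pathlib.Path]) -> None:
    """Write constants as a flat key-value file (YAML or JSON by suffix)."""
    path = pathlib.Path(path)
    payload = dataclasses.asdict(constants)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_constants(path: Union[str, pathlib.Path]) -> ModelConstants:
    """Read constants written by :func:`save_constants`."""
    path = pathlib.Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(ModelConstants)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown model constants: {sorted(unknown)}")
    return ModelConstants(**payload)
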