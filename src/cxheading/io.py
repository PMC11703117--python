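"""Serialisation, configuration and seed plumbing for reproducible runs.

Weight sets travel as versioned CSV matrices whose rows are labelled
``<block>:<postsynaptic neuron>`` and whose columns name the presynaptic
neurons; the connectivity masks are stored in the same file, so a weight
file is self-describing. Values round-trip bit-exactly (floats are
written in shortest-roundtrip representation).

One master seed expands deterministically into independent per-stage
seeds via ``numpy.random.SeedSequence`` spawning, so partial re-runs of
a pipeline see the same streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .circuit import (
    N_COLUMNAR,
    N_PRE,
    ConnectivityMask,
    SimulationResult,
    WeightSet,
    neuron_names,
)
from .constants import ModelConstants
from .exceptions import WeightFormatError
from .training import TrainingConfig, TrainingReport

__all__ = [
    "save_weights",
    "load_weights",
    "save_mask",
    "load_mask",
    "simulation_to_frame",
    "training_report_to_frame",
    "spawn_seeds",
    "write_manifest",
    "load_run_config",
]

_WEIGHTS_MAGIC = "# cxheading-weights v1"
_MASK_MAGIC = "# cxheading-mask v1"
_WEIGHT_BLOCKS = ("g_s", "g_mod_cw", "g_mod_ccw", "mask_ff", "mask_mod")


def _stack_blocks(blocks: Dict[str, np.ndarray]) -> pd.DataFrame:
    cols = neuron_names(include_bias=True)
    post = neuron_names(include_bias=False)
    frames = []
    for name, matrix in blocks.items():
        df = pd.DataFrame(
            np.asarray(matrix, dtype=float),
            index=[f"{name}:{p}" for p in post],
            columns=cols,
        )
        frames.append(df)
    return pd.concat(frames)


def save_weights(weights: WeightSet, path: Union[str, pathlib.Path]) -> None:
    """Write a weight set (and its masks) as a versioned CSV file."""
    path = pathlib.Path(path)
    df = _stack_blocks(
        {
            "g_s": weights.g_s,
            "g_mod_cw": weights.g_mod_cw,
            "g_mod_ccw": weights.g_mod_ccw,
            "mask_ff": weights.mask.ff_mask.astype(float),
            "mask_mod": weights.mask.mod_mask.astype(float),
        }
    )
    with open(path, "w") as fh:
        fh.write(_WEIGHTS_MAGIC + "\n")
        df.to_csv(fh, index_label="row", float_format="%.17g")


def _read_versioned_csv(path: pathlib.Path, magic: str) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != magic:
            raise WeightFormatError(
                f"{path}: expected header {magic!r}, found {first!r}"
            )
        return pd.read_csv(fh, index_col="row", float_precision="round_trip")


def _extract_block(df: pd.DataFrame, name: str, path) -> np.ndarray:
    post = neuron_names(include_bias=False)
    want = [f"{name}:{p}" for p in post]
    missing = [r for r in want if r not in df.index]
    if missing:
        raise WeightFormatError(
            f"{path}: block {name!r} is incomplete (missing {missing[0]}, ...)"
        )
    block = df.loc[want]
    cols = neuron_names(include_bias=True)
    if list(block.columns) != cols:
        raise WeightFormatError(f"{path}: presynaptic column names do not match")
    out = block.to_numpy(dtype=float)
    if out.shape != (N_COLUMNAR, N_PRE):
        raise WeightFormatError(f"{path}: block {name!r} has shape {out.shape}")
    return out


def load_weights(
    path: Union[str, pathlib.Path],
    expected_mask: Optional[ConnectivityMask] = None,
) -> WeightSet:
    """Read a weight set written by :func:`save_weights`.

    Raises :class:`~cxheading.exceptions.WeightFormatError` on a version
    mismatch, a missing block (e.g. a file without the modulatory
    weights), or — when ``expected_mask`` is given — a mask that does
    not match the expectation.
    """
    path = pathlib.Path(path)
    df = _read_versioned_csv(path, _WEIGHTS_MAGIC)
    blocks = {name: _extract_block(df, name, path) for name in _WEIGHT_BLOCKS}
    mask = ConnectivityMask(
        blocks["mask_ff"].astype(bool), blocks["mask_mod"].astype(bool)
    )
    if expected_mask is not None and (
        not np.array_equal(mask.ff_mask, expected_mask.ff_mask)
        or not np.array_equal(mask.mod_mask, expected_mask.mod_mask)
    ):
        raise WeightFormatError(f"{path}: stored mask differs from the expected mask")
    try:
        return WeightSet(
            mask, blocks["g_s"], blocks["g_mod_cw"], blocks["g_mod_ccw"]
        )
    except ValueError as exc:
        raise WeightFormatError(f"{path}: {exc}") from exc


def save_mask(mask: ConnectivityMask, path: Union[str, pathlib.Path]) -> None:
    """Write a connectivity mask as a versioned CSV file (0/1 matrices)."""
    path = pathlib.Path(path)
    df = _stack_blocks(
        {"mask_ff": mask.ff_mask.astype(float), "mask_mod": mask.mod_mask.astype(float)}
    )
    with open(path, "w") as fh:
        fh.write(_MASK_MAGIC + "\n")
        df.to_csv(fh, index_label="row", float_format="%.17g")


def load_mask(path: Union[str, pathlib.Path]) -> ConnectivityMask:
    path = pathlib.Path(path)
    df = _read_versioned_csv(path, _MASK_MAGIC)
    ff = _extract_block(df, "mask_ff", path).astype(bool)
    mod = _extract_block(df, "mask_mod", path).astype(bool)
    return ConnectivityMask(ff, mod)


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def simulation_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Long-format rate trajectory: columns (t_ms, neuron, rate_hz)."""
    names = neuron_names(include_bias=False) + ["AV_CW", "AV_CCW"]
    n_t, n_n = result.rates.shape
    return pd.DataFrame(
        {
            "t_ms": np.repeat(result.t, n_n),
            "neuron": np.tile(names, n_t),
            "rate_hz": result.rates.ravel(),
        }
    )


def training_report_to_frame(report: TrainingReport) -> pd.DataFrame:
    """Training log: columns (iteration, loss, data_term, reg_term)."""
    return pd.DataFrame(
        report.as_rows(), columns=["iteration", "loss", "data_term", "reg_term"]
    )


# ---------------------------------------------------------------------------
# seeds, manifests, run configuration
# ---------------------------------------------------------------------------

def spawn_seeds(master_seed: int, n: int) -> List[int]:
    """Expand one master seed into ``n`` independent stage seeds (< 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def write_manifest(
    path: Union[str, pathlib.Path],
    command: str,
    seed: int,
    config: Optional[dict] = None,
    outputs: Optional[dict] = None,
) -> None:
    """JSON run manifest: command, seed, config hash, package version."""
    config = config or {}
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "cxheading",
        "version": _pkg_version,
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "outputs": outputs or {},
    }
    pathlib.Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def load_run_config(path: Union[str, pathlib.Path]) -> dict:
    """Read a YAML/JSON run configuration.

    Recognised top-level sections: ``constants`` (ModelConstants fields)
    and ``training`` (TrainingConfig fields); both are optional and are
    returned as instantiated objects alongside any remaining sections.
    """
    path = pathlib.Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    out = dict(raw)
    if "constants" in raw:
        out["constants"] = ModelConstants(**raw["constants"])
    if "training" in raw:
        out["training"] = TrainingConfig(**raw["training"])
    return out


def config_as_dict(obj) -> dict:
    """Dataclass -> plain dict (for manifests)."""
    return dataclasses.asdict(obj)
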