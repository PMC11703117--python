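"""Shared helper: train the joint-modulation network once and cache it.

The first example run trains the circuit (a few minutes); subsequent
runs reuse ``examples/weights.csv``.
"""

import pathlib

from cxheading import build_columnar_mask, load_weights, optimize, save_weights

WEIGHTS_PATH = pathlib.Path(__file__).parent / "weights.csv"


def get_trained_weights(seed: int = 1):
    if WEIGHTS_PATH.exists():
        print(f"loading cached weights from {WEIGHTS_PATH}")
        return load_weights(WEIGHTS_PATH)
    print("training the heading circuit (L-BFGS, a few minutes) ...")
    weights, report = optimize(build_columnar_mask(), seed=seed)
    print(f"  final training loss: {report.final_loss:.4g}")
    save_weights(weights, WEIGHTS_PATH)
    return weights
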