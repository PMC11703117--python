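"""Exception types shared across the package."""


class DegenerateCircuitError(ArithmeticError):
    """The denominator of the steady-state potential fell below its guard.

    Raised when ``1 + sum(g_tot * P_s)`` drops to (or below) the configured
    epsilon, which identifies pathological weight configurations where the
    shunting membrane equation loses meaning.
    """


class UndefinedPhaseError(ValueError):
    """Cosine decoding was attempted on an activity profile with no bump.

    Raised when the amplitude of the best-fitting cosine is below the
    configured epsilon, so the phase (decoded heading) is undefined.
    """


class WeightFormatError(ValueError):
    """A weight file does not match the expected versioned CSV format."""
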