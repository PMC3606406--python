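"""Exception hierarchy for splaynet."""


class SplaynetError(Exception):
    """Base class for all splaynet errors."""


class NotFiringError(SplaynetError):
    """Neuron 1 never reaches threshold within the time cap.

    Signals a non-positive total drive (e.g. strongly inhibitory coupling)
    along the trajectory, so the network dynamics is not firing.
    """


class OrderingError(SplaynetError):
    """Strict ordering of the membrane potentials was violated.

    Two neurons would cross threshold simultaneously (avalanche), which the
    event-driven map does not support.
    """


class ExistenceError(SplaynetError):
    """No splay-state fixed point exists for the requested parameters."""


class ConfigError(SplaynetError):
    """A configuration file violates the expected schema."""


class SpectrumError(SplaynetError):
    """Floquet mode assignment failed (ambiguous multiplier-to-mode map)."""
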