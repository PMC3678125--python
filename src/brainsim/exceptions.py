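"""Exception hierarchy for brainsim.

All configuration and validation failures derive from :class:`ValueError`
so that callers can catch them uniformly, while still being able to tell a
malformed input file from an inconsistent simulation set-up.
"""


class ConnectomeFormatError(ValueError):
    """A connectome archive is missing a mandatory file or is unparseable."""


class DimensionError(ValueError):
    """Array shapes do not match the declared network/model dimensions."""


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


class SimulationDivergenceError(RuntimeError):
    """The integrated state left the admissible range (numerical blow-up)."""

    def __init__(self, step: int, node: int, message: str | None = None):
        self.step = step
        self.node = node
        super().__init__(
            message
            or f"non-finite or diverging state at integration step {step}, node {node}"
        )
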