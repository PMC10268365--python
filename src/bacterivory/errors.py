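"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InputError(ValueError):
    """An input table is malformed or missing required content."""


class DegenerateInputError(ValueError):
    """Input is syntactically valid but the operation is undefined on it
    (e.g. a flat growth curve, an all-zero composition)."""
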