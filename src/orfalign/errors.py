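"""Exception hierarchy for orfalign."""


class OrfAlignError(Exception):
    """Base class for all orfalign errors."""


class InputError(OrfAlignError, ValueError):
    """Malformed user input (sequences, files, alignments)."""


class ConfigError(OrfAlignError, ValueError):
    """Invalid configuration (unknown genetic code, bad penalties...)."""


class ParameterError(OrfAlignError, ValueError):
    """Invalid simulation / refinement parameter."""


class InvalidColumnError(OrfAlignError, ValueError):
    """An alignment column violates a structural invariant (e.g. all-gap)."""


class OracleSizeError(OrfAlignError, ValueError):
    """Brute-force oracle refused an input that is too large to enumerate."""
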