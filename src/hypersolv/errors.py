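"""Exception hierarchy used across the package."""


class HypersolvError(Exception):
    """Base class for all package-specific errors."""


class InputError(HypersolvError):
    """Invalid user input (bad SMILES, missing labels, empty corpus...)."""


class FormatError(HypersolvError):
    """Malformed file contents (missing columns, bad vocabulary records)."""


class ConfigError(HypersolvError):
    """Inconsistent configuration (width mismatches, impossible capacities)."""


class CheckpointError(HypersolvError):
    """Checkpoint incompatible with the requested configuration/vocabulary."""
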