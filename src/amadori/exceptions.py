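"""Exception hierarchy for the amadori package."""


class AmadoriError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmadoriError, ValueError):
    """Invalid configuration value (unknown reference standard, bad tolerance, ...)."""


class PeakListParseError(AmadoriError, ValueError):
    """A peak-list file could not be parsed; message names the offending line."""


class AxisOrderError(PeakListParseError):
    """Chemical-shift columns appear transposed (13C values inside the 1H window)."""


class SpectrumFormatError(AmadoriError, ValueError):
    """Gridded-spectrum container is malformed (header/matrix mismatch, bad axis)."""


class SequenceError(AmadoriError, ValueError):
    """Protein sequence contains residues outside the 20 one-letter codes."""


class QuantificationError(AmadoriError, ValueError):
    """Stoichiometry cannot be computed (missing reference class, no presence call)."""
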