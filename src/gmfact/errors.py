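"""Exception hierarchy for gmfact.

Exit-code mapping used by the CLI: configuration errors -> 2,
numerical failures -> 3.
"""


class GMFError(Exception):
    """Base class for all gmfact errors."""


class GMFConfigError(GMFError, ValueError):
    """Invalid configuration: unknown family/link, bad hyperparameters,
    shape mismatches, rank-deficient designs."""


class GMFDomainError(GMFError, ValueError):
    """Responses or means outside the family domain."""


class GMFNumericalError(GMFError, RuntimeError):
    """Non-finite objective, diverging fit, or singular inner solve."""
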