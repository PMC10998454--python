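"""Exception hierarchy for gwaspower."""


class GwasPowerError(Exception):
    """Base class for all package-specific errors."""


class ModelInfeasibleError(GwasPowerError):
    """No baseline odds satisfies the prevalence constraint for the given odds ratios."""


class InfeasibleTargetError(GwasPowerError):
    """Calibration target power exceeds what the design can achieve."""


class StructuralError(GwasPowerError):
    """Inconsistent dataset structure (e.g. mismatched group sizes across SNPs)."""


class FormatError(GwasPowerError):
    """Malformed input file."""
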