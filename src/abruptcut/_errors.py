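"""Exception hierarchy shared across the pipeline stages."""


class AbruptcutError(Exception):
    """Base class for all pipeline errors."""


class InputError(AbruptcutError):
    """Unreadable or malformed input file."""


class ParameterError(AbruptcutError):
    """A configuration value violates a module precondition."""


class EmptyMaskError(AbruptcutError):
    """A mask with no foreground pixels where one is required."""


class EmptyRegionError(AbruptcutError):
    """A sampling region with no pixels where statistics were requested."""


class ChainIntegrityError(AbruptcutError):
    """A chain code that does not close back onto its start pixel."""


class DegenerateContractionError(AbruptcutError):
    """Inner-border contraction collapsed: a boundary point lies within the
    contraction distance of the centroid (the documented vector-shift
    failure mode)."""


class FeatureExtractionError(AbruptcutError):
    """No valid sampling region survived for some radius."""
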