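"""Exception hierarchy.

All package-specific failures derive from :class:`MesmarkError` so callers
can catch one base class at pipeline boundaries.
"""


class MesmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MesmarkError):
    """Invalid parameter values (non-positive sizes, bad modes, zero weights)."""


class ParseError(MesmarkError):
    """Malformed text input; message names the offending line when known."""


class ValidationError(MesmarkError):
    """Structurally valid input that violates a model invariant
    (out-of-bounds coordinates, duplicate ids, mismatched universes)."""


class PlacementError(MesmarkError):
    """A simulated feature cannot be placed on the genome."""


class NormalizationError(MesmarkError):
    """A coverage track cannot be scaled (for instance, all-zero signal)."""


class StateError(MesmarkError):
    """An operation applied to tracks in the wrong normalization state."""
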