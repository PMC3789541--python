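"""Exception hierarchy.

Everything raised on purpose derives from :class:`WoundkitError` so callers
can catch the whole family; the leaves distinguish validation failures,
file-format problems, assignment conflicts and capability gaps.
"""


class WoundkitError(Exception):
    """Base class for all errors raised by woundkit."""


class ValidationError(WoundkitError, ValueError):
    """A domain invariant is violated (named in the message)."""


class AddressError(ValidationError):
    """A well address falls outside the plate geometry."""


class ConflictError(WoundkitError):
    """An exclusive resource (well, label, plugin name) is already taken."""


class FormatError(WoundkitError, ValueError):
    """A per-well text file does not follow the expected dialect."""


class SchemaError(WoundkitError, ValueError):
    """An XML document fails well-formedness or schema validation."""


class GridError(WoundkitError, ValueError):
    """Trajectories share too few time points to be compared."""


class StateError(WoundkitError, RuntimeError):
    """An operation was invoked before its prerequisite step."""


class ResolutionError(WoundkitError):
    """QC flags remain without an accept/reject decision."""


class CapabilityError(WoundkitError, RuntimeError):
    """An optional renderer or backend is not installed."""
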