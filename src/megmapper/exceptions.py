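"""Exception hierarchy shared across the pipeline."""


class MegMapperError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(MegMapperError, ValueError):
    """A simulation or Mapper configuration violates its invariants."""


class DataError(MegMapperError, ValueError):
    """Input data is malformed: non-finite values, missing labels, bad fixture."""


class EmptyOutputError(MegMapperError, ValueError):
    """A filtering step removed every row."""


class IncompatibleInputsError(MegMapperError, ValueError):
    """Two inputs cannot be combined (e.g. empty channel intersection)."""


class UnsupportedOperationError(MegMapperError, ValueError):
    """A requested operation is outside the supported envelope (e.g. upsampling)."""


class InsufficientDataError(MegMapperError, ValueError):
    """Too few subjects or pairs for the requested statistical procedure."""


class UsageError(MegMapperError, ValueError):
    """An argument is outside the documented domain."""
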