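"""Exception hierarchy for smartscan."""


class SmartError(Exception):
    """Base class for all smartscan errors."""


class SchemaError(SmartError):
    """Input table violates the expected schema (columns, ids, types)."""


class PairingError(SmartError):
    """Case-control pairing or baseline/repeated structure is broken."""


class MetadataError(SmartError):
    """Required per-sample metadata is missing or inconsistent."""


class DegenerateVariableError(SmartError):
    """A variable has zero variance and cannot be scaled."""


class SampleSizeError(SmartError):
    """Too few observations for the requested model."""


class RankError(SmartError):
    """Requested more components than the data rank supports."""
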