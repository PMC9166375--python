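"""Exception types shared across the pipeline."""


class DocsubreError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(DocsubreError):
    """A PubTator block or tabular row violates the format contract."""


class ParseStructureError(DocsubreError):
    """A CoNLL-U sentence is not a single-rooted dependency tree."""


class AlignmentError(DocsubreError):
    """An entity mention cannot be mapped onto parsed tokens."""


class ConfigurationError(DocsubreError):
    """A configuration value is outside its admissible range."""
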