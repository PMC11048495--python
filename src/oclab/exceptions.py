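"""Typed errors raised across the toolkit.

Every parsing, configuration and degenerate-input failure maps to one of
these classes so callers (and tests) can distinguish "your file is broken"
from "your parameters are inconsistent" from "this input is mathematically
degenerate".
"""


class OclabError(Exception):
    """Base class for all toolkit errors."""


class FormatError(OclabError, ValueError):
    """A file does not conform to its declared dialect (KEEL, delimited, JSON)."""


class LabelError(OclabError, ValueError):
    """A class label could not be mapped to positive/negative."""


class ConfigError(OclabError, ValueError):
    """Parameters are out of range or mutually inconsistent."""


class SummaryError(OclabError, ValueError):
    """A dataset summary is undefined (e.g. single-class data)."""


class DegenerateInputError(OclabError, ValueError):
    """The input is valid but the requested quantity is undefined on it."""
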