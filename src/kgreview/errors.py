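"""Exception hierarchy shared across the package.

Validation / configuration problems map to CLI exit status 1,
I/O problems to exit status 2.
"""


class KgReviewError(Exception):
    """Base class for all package errors."""


class MalformedIdentifierError(KgReviewError, ValueError):
    """A compact identifier (CURIE) string does not parse."""


class ValidationError(KgReviewError, ValueError):
    """A record, template or specification violates an invariant."""


class DialectError(KgReviewError, ValueError):
    """A tabular file does not match the expected column dialect."""


class ConfigurationError(KgReviewError, ValueError):
    """A review configuration is inconsistent or incomplete."""


class PrefixError(KgReviewError, KeyError):
    """A CURIE prefix has no URI base in the prefix map."""


class InputError(KgReviewError, OSError):
    """A declared input file is missing or unreadable."""
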