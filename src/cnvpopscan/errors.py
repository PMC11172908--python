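"""Exception hierarchy.

All package errors derive from :class:`CnvPopScanError` so callers can catch
one type at pipeline boundaries while tests can assert on the specific class.
"""


class CnvPopScanError(Exception):
    """Base class for all cnvpopscan errors."""


class ConfigurationError(CnvPopScanError):
    """Invalid parameter values or run configuration (bad thresholds, unknown keys)."""


class InputError(CnvPopScanError):
    """Malformed or degenerate input data (empty matrix, all-zero sample, empty group)."""


class SpecificationError(CnvPopScanError):
    """A synthetic-truth or annotation specification that cannot be realized
    on the given genome (off-genome region, overlapping regions, features that
    do not fit)."""


class AnnotationError(CnvPopScanError):
    """A genotyping/annotation request on an interval with no usable windows."""
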