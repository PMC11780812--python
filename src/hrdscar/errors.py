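"""Exception types shared across the package."""


class HrdscarError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HrdscarError):
    """Invalid input data (malformed table, violated invariant).

    Messages identify the offending sample/chromosome/row wherever the
    violation is row-local, so users can fix their tables.
    """


class ConvergenceError(HrdscarError):
    """An iterative fit failed to converge; carries diagnostics in the message."""
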