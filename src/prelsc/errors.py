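"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` → 2,
:class:`BoundaryError` → 3.
"""


class PreLscError(Exception):
    """Base class for all package-specific errors."""


class InputError(PreLscError, ValueError):
    """Invalid or malformed user input (bad file, out-of-range value...)."""


class BoundaryError(PreLscError):
    """A statistic is undefined at a boundary condition.

    E.g. a frequency ratio requested for an all-negative cohort whose
    maximum-likelihood frequency is exactly zero.
    """
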