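"""Exception hierarchy shared across the pipeline.

Validation problems (bad input files, contract violations) raise
:class:`ValidationError`; numerical failures that are not the user's fault
raise :class:`NumericalError`.  The CLI maps these to exit codes 2 and 3.
"""


class RscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(RscoreError):
    """Input data or configuration violates a documented contract."""


class NumericalError(RscoreError):
    """A numerical routine failed to produce a usable result."""


class NoValidCutoff(NumericalError):
    """No admissible expression cutoff exists for the survival scan."""
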