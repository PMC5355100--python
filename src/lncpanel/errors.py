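"""Exception hierarchy.

``InputError`` marks problems with user-supplied data or configuration
(CLI exit code 1); anything else escaping the library is treated as an
internal error (CLI exit code 2).
"""


class LncPanelError(Exception):
    """Base class for all lncpanel errors."""


class InputError(LncPanelError):
    """Invalid user input: malformed table, bad config, missing ids."""


class ConvergenceError(LncPanelError):
    """An iterative fit failed to converge."""
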