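"""Package-level exception types."""


class ReglinkError(ValueError):
    """Raised for domain-level validation and pipeline failures.

    The CLI maps this to a one-line diagnostic and exit code 1; library
    users can catch it as an ordinary ``ValueError``.
    """
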