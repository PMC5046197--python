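"""Exceptions raised by the phasing toolkit."""


class FragmentFormatError(ValueError):
    """A fragment file violates the dialect or a matrix invariant."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class CoverageLimitError(RuntimeError):
    """A column's bipartition table would exceed the hard coverage limit.

    The dynamic program allocates 2**c states for a column of coverage c;
    refusing is preferable to thrashing memory.
    """
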