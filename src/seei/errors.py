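"""Exception types shared across the package."""


class DataError(ValueError):
    """Malformed or invalid genotype data."""


class EmptyAfterQCError(DataError):
    """Quality control removed every sample or (almost) every SNP."""


class InfeasibleModelError(RuntimeError):
    """A penetrance model cannot populate both the case and control pools."""
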