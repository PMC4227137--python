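"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited format."""


class SignatureMatchError(ValueError):
    """Too few signature genes are present in an expression matrix."""


class ZeroCellError(ValueError):
    """A 2x2 table has an empty cell and no continuity correction was requested."""
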