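"""Structured exceptions shared by all pipeline stages."""


class Type3Error(Exception):
    """Base class for all errors raised by this package."""


class FormatError(Type3Error):
    """Malformed input file (FASTA/GFF3/BED/TSV/newick)."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class DataError(Type3Error):
    """Input is well-formed but violates a pipeline invariant."""


class TreeError(Type3Error):
    """Invalid tree operation or degenerate tree input."""


class ConfigError(Type3Error):
    """Invalid configuration key or value."""
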