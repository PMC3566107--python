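"""Exception hierarchy shared across nanomap modules."""


class NanomapError(Exception):
    """Base class for all nanomap errors."""


class ValidationError(NanomapError):
    """Invalid input data or parameters."""


class FormatError(ValidationError):
    """Malformed on-disk file. Carries an optional line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ClusteringError(NanomapError):
    """Molecule clustering could not proceed (e.g. no usable molecules)."""


class AlignmentError(NanomapError):
    """Map alignment / merging failure (e.g. contradictory overlaps)."""
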