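"""Exception hierarchy shared across the package."""


class FesipError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FesipError):
    """Invalid configuration value (non-physical volume, bad schedule...)."""


class MeasurementInconsistencyError(FesipError):
    """A measured series violates a physical constraint (e.g. Fe(II) > total Fe)."""


class UndefinedRatioError(FesipError):
    """A ratio with a zero denominator was requested (zero electron production,
    zero control mean, zero added label)."""


class DegenerateProfileError(FesipError):
    """A gradient profile with no signal cannot be normalized."""


class PairingError(FesipError):
    """Two gradient profiles share no overlapping buoyant-density range."""


class SchemaError(FesipError):
    """A tabular input file violates its documented schema."""

    def __init__(self, message: str, path=None, line=None, column=None):
        loc = []
        if path is not None:
            loc.append(f"file={path}")
        if line is not None:
            loc.append(f"line={line}")
        if column is not None:
            loc.append(f"column={column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path = path
        self.line = line
        self.column = column
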