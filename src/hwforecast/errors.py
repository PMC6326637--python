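"""Exception hierarchy shared across the pipeline.

Every error raised on a user-facing path derives from :class:`ForecastError`
so callers (and the CLI) can distinguish pipeline failures from programming
errors and map them to exit codes.
"""


class ForecastError(Exception):
    """Base class for all hwforecast errors."""

    exit_code = 1


class ValidationError(ForecastError):
    """An input value violates a model invariant (negative count, p outside [0,1], ...)."""

    exit_code = 2


class MissingDataError(ForecastError):
    """A required cell (region, year, category, staff type) is absent from an input."""

    exit_code = 3


class SchemaError(ForecastError):
    """A CSV/JSON input does not match its declared schema.

    Carries file / row / column context when available so messages point at
    the offending cell.
    """

    exit_code = 4

    def __init__(self, message: str, *, path: str | None = None,
                 row: int | None = None, column: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = " @ ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.row = row
        self.column = column


class ConfigError(ForecastError):
    """A run configuration is invalid (missing file, horizon < 1, bad mode...)."""

    exit_code = 5
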