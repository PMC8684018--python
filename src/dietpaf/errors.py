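"""Error taxonomy; the CLI maps each class to a distinct exit code."""


class DietPafError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(DietPafError):
    """Invalid run configuration (bad paths, enums, band sets)."""

    exit_code = 2


class DataError(DietPafError):
    """Invalid or inconsistent input data (schema, duplicates, marginals)."""

    exit_code = 3


class ComputationError(DietPafError):
    """Contract violation during computation (empty stratum, missing cell)."""

    exit_code = 4
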