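"""Exception types shared across the package."""


class CapColonyError(Exception):
    """Base class for all package-specific errors."""


class SolverError(CapColonyError):
    """Iterative geometry solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, **diagnostics):
        super().__init__(message)
        self.diagnostics = dict(diagnostics)


class ConfigError(CapColonyError):
    """Run-configuration file failed validation."""
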