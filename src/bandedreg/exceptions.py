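"""Exception hierarchy for bandedreg."""


class BandedRegError(Exception):
    """Base class for all bandedreg errors."""


class DimensionError(BandedRegError, ValueError):
    """Inconsistent array shapes (row counts, column counts, group ranges)."""


class DomainError(BandedRegError, ValueError):
    """Parameter outside its mathematical domain (e.g. h <= 0, alpha <= 0)."""


class NumericalError(BandedRegError, RuntimeError):
    """Numerical failure: non-positive-definite system after jitter, NaN/Inf mid-fit."""


class ConfigError(BandedRegError, ValueError):
    """Malformed run configuration (missing keys, inconsistent group spec)."""
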