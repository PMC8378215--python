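"""Exception hierarchy."""


class NozzleFlowError(Exception):
    """Base class for all package errors."""


class UnknownMaterialError(KeyError, NozzleFlowError):
    """Material name not found in the built-in library."""


class GeometryError(ValueError, NozzleFlowError):
    """Invalid nozzle geometry (non-positive dimension, bad shape tag)."""


class GeometryConstraintError(GeometryError):
    """Conical geometry violating R_big > R_middle > R_small ordering."""


class DriveError(ValueError, NozzleFlowError):
    """Invalid drive condition."""


class MeshError(ValueError, NozzleFlowError):
    """Grid spacing incompatible with the geometry."""


class ConvergenceError(NozzleFlowError):
    """Iterative solver failed to reach the residual target."""


class DivergenceError(ConvergenceError):
    """Iterative solver produced NaN/Inf; reduce relaxation."""


class CampaignError(NozzleFlowError):
    """Too many solver failures inside a DoE campaign."""


class ConfigError(ValueError, NozzleFlowError):
    """Run configuration failed schema validation."""
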