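"""Blood rheology parameters.

Blood is treated as an incompressible Newtonian fluid in steady laminar flow.
Defaults are typical literature values for whole blood at body temperature;
both are configurable, and the correction-factor calibration partially absorbs
any residual mismatch.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class Fluid:
    """Newtonian fluid properties.

    Attributes
    ----------
    rho : float
        Density in kg/m^3 (default 1050, whole blood).
    mu : float
        Dynamic viscosity in Pa*s (default 3.5e-3, whole blood).
    """

    rho: float = 1050.0
    mu: float = 3.5e-3

    def __post_init__(self):
        if not (self.rho > 0):
            raise ValueError(f"density must be positive, got {self.rho}")
        if not (self.mu > 0):
            raise ValueError(f"viscosity must be positive, got {self.mu}")


BLOOD = Fluid()
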