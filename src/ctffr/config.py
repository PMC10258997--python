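"""YAML/JSON run configuration.

Recognized keys (all optional; defaults in parentheses):
rho (1050), mu (3.5e-3), P_a_rest_mmHg (100), omega (0.9), P_v_mmHg (6.5),
hyperemic_fraction (0.24), lvmm_g (139), dominance ('right'), side ('left'),
flow_scale_L_min_per_g, lvmm_exponent (1), left_fraction_right_dominant,
left_fraction_left_codominant, murray_exponent (3), stenosis_beta (0.05,
as a fraction), spacing_m (3e-4), tol_mmHg (1e-3), max_iter (200),
smooth_window (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .boundary import DEFAULT_FLOW_SCALE_L_MIN_PER_G, DEFAULT_LEFT_FRACTION, PatientParams
from .fluid import Fluid
from .solver import SolverOptions


@dataclass
class RunConfig:
    fluid: Fluid = field(default_factory=Fluid)
    patient: PatientParams = field(default_factory=PatientParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    spacing_m: float = 3e-4
    stenosis_beta: float = 0.05     # fraction; 0.05 = 5% stenosis threshold
    smooth_window: int = 3

    @property
    def beta_percent(self) -> float:
        return 100.0 * self.stenosis_beta


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
    if overrides:
        doc.update(overrides)

    fluid = Fluid(rho=doc.get("rho", 1050.0), mu=doc.get("mu", 3.5e-3))
    fractions = dict(DEFAULT_LEFT_FRACTION)
    if "left_fraction_right_dominant" in doc:
        fractions["right"] = float(doc["left_fraction_right_dominant"])
    if "left_fraction_left_codominant" in doc:
        fractions["left_or_co"] = float(doc["left_fraction_left_codominant"])
    patient = PatientParams(
        lvmm=doc.get("lvmm_g", 139.0),
        dominance=doc.get("dominance", "right"),
        P_a_rest=doc.get("P_a_rest_mmHg", 100.0),
        omega=doc.get("omega", 0.9),
        P_v=doc.get("P_v_mmHg", 6.5),
        hyperemic_fraction=doc.get("hyperemic_fraction", 0.24),
        flow_scale=doc.get("flow_scale_L_min_per_g",
                           DEFAULT_FLOW_SCALE_L_MIN_PER_G),
        lvmm_exponent=doc.get("lvmm_exponent", 1.0),
        left_fractions=fractions,
        murray_exponent=doc.get("murray_exponent", 3.0),
        side=doc.get("side", "left"),
    )
    solver = SolverOptions(tol_mmHg=doc.get("tol_mmHg", 1e-3),
                           max_iter=int(doc.get("max_iter", 200)))
    return RunConfig(fluid=fluid, patient=patient, solver=solver,
                     spacing_m=doc.get("spacing_m", 3e-4),
                     stenosis_beta=doc.get("stenosis_beta", 0.05),
                     smooth_window=int(doc.get("smooth_window", 3)))
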