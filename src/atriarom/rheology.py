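"""Blood rheology: Newtonian and Casson constitutive laws.

Whole blood is shear-thinning with a small yield stress.  The Casson model
expresses the effective dynamic viscosity as a function of the second
invariant J2 of the strain-rate tensor D = (grad v + grad v^T)/2,

    mu(J2) = [ (eta_bar^2 J2)^(1/4) + (tau_y / 2)^(1/2) ]^2 * J2^(-1/2),

with eta_bar = eta / (1 - H/100)^2.5 the Einstein-corrected plasma viscosity
and tau_y = (a1 + a2 * H/100)^3 the hematocrit-driven yield stress
(a1 = 0, a2 = 0.290 Pa^(1/3) for blood).  The shear rate is gamma = 2 sqrt(J2).
At H = 0 the law reduces exactly to the Newtonian one with mu = eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Casson coefficients for whole blood
A1 = 0.0
A2 = 0.290  # Pa^(1/3)


@dataclass
class RheologyParams:
    """Constitutive model and material constants.

    ``hematocrit`` is stored in percent (e.g. 45 means a red-cell volume
    fraction of 0.45).  ``j2_min`` regularizes the yield-stress singularity of
    the Casson law at vanishing strain rate.  ``casson_form`` selects the
    standard law (outer exponent 2, Newtonian limit exact) or a square-root
    variant ("sqrt") that appears in some transcriptions of the model and does
    not reduce to a constant viscosity at zero yield stress.
    """

    model: str = "newtonian"
    density: float = 1050.0            # kg/m^3
    mu_newtonian: float = 0.0035       # Pa s
    plasma_viscosity: float = 1.6e-3   # Pa s (Casson)
    hematocrit: float = 45.0           # percent (Casson)
    j2_min: float = 1e-12              # s^-2
    casson_form: str = "standard"

    def __post_init__(self):
        if self.model not in ("newtonian", "casson"):
            raise ValueError(f"unknown rheology model {self.model!r}")
        if self.casson_form not in ("standard", "sqrt"):
            raise ValueError(f"unknown casson_form {self.casson_form!r}")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma viscosity must be positive")
        if not 0 <= self.hematocrit < 100:
            raise ValueError("hematocrit (percent) must lie in [0, 100)")
        if self.j2_min <= 0:
            raise ValueError("j2_min must be positive")

    @property
    def eta_bar(self) -> float:
        """Effective asymptotic viscosity eta / (1 - H)^2.5, H as a fraction."""
        return self.plasma_viscosity / (1.0 - self.hematocrit / 100.0) ** 2.5

    @property
    def tau_y(self) -> float:
        """Casson yield stress (a1 + a2 H)^3, H as a fraction (Pa)."""
        return (A1 + A2 * self.hematocrit / 100.0) ** 3


def yield_stress(rheology: RheologyParams) -> float:
    """Yield stress tau_y of the Casson law (Pa)."""
    return rheology.tau_y


def effective_viscosity(j2, rheology: RheologyParams):
    """Effective dynamic viscosity (Pa s) at strain-rate invariant ``j2`` (s^-2).

    Newtonian: the constant ``mu_newtonian``.  Casson: the regularized law
    evaluated at max(j2, j2_min); continuous, strictly positive, monotone
    non-increasing in j2, with mu -> eta_bar as j2 -> infinity.
    """
    j2 = np.asarray(j2, dtype=float)
    if np.any(j2 < 0):
        raise ValueError("J2 must be non-negative")
    if rheology.model == "newtonian":
        out = np.full_like(j2, rheology.mu_newtonian)
        return float(out) if out.ndim == 0 else out
    j2r = np.maximum(j2, rheology.j2_min)
    core = (rheology.eta_bar ** 2 * j2r) ** 0.25 + (rheology.tau_y / 2.0) ** 0.5
    outer = 0.5 if rheology.casson_form == "sqrt" else 2.0
    out = core ** outer / np.sqrt(j2r)
    return float(out) if out.ndim == 0 else out
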