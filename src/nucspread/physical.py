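"""Derivation of the kinetic rate constants from physical constants.

The model's rates are not fitted: each is derived from measured biophysical
quantities.  Enzyme arrival at a DNA site is treated as a diffusion-limited
(Smoluchowski) association scaled by the nuclear enzyme copy number; 1D
sliding maps the measured on-chromatin diffusion coefficient to a
nucleosome-to-nucleosome hop rate; the dissociation rate is the reciprocal
of the FRAP residence time.  The dimensionless recruitment efficiency (RE)
summarises the feedback strength: the lifetime of a mark divided by the mean
waiting time for a recruitment event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "diffusion_limited_association",
    "slide_rate",
    "off_rate_from_residence",
    "recruitment_efficiency",
    "k_recruitment_for_re",
    "table1_report",
]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Biophysical inputs to the rate derivations.

    Attributes
    ----------
    D_E, D_S : float
        Diffusion coefficients of the enzyme and of the DNA binding site,
        µm²/s.  Nuclear enzyme mobility is in the 0.5–5 µm²/s range; the
        site's mobility is orders of magnitude smaller and may be set to 0.
    r_E, r_S : float
        Radii of enzyme and binding site, µm (a ~5 nm transferase and a
        15 bp ~5 nm site give 0.0025 each).
    n_E : float
        Modification-enzyme copies per nucleus.
    V_nucleus : float
        Nuclear volume, µm³ (500 µm³ for an average human nucleus).
    D_1d : float
        1D sliding diffusion coefficient on chromatin, µm²/s.
    d_spacing : float
        Nucleosome-to-nucleosome distance, µm (~0.025).
    residence_time : float
        Mean chromatin-bound residence time of the transferase, s.
    """

    D_E: float = 3.8
    D_S: float = 0.0
    r_E: float = 0.0025
    r_S: float = 0.0025
    n_E: float = 5000.0
    V_nucleus: float = 500.0
    D_1d: float = 2e-4
    d_spacing: float = 0.025
    residence_time: float = 10.0

    def __post_init__(self) -> None:
        _require_positive(
            r_E=self.r_E,
            r_S=self.r_S,
            n_E=self.n_E,
            V_nucleus=self.V_nucleus,
            D_1d=self.D_1d,
            d_spacing=self.d_spacing,
            residence_time=self.residence_time,
        )
        for name in ("D_E", "D_S"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")


def diffusion_limited_association(pc: PhysicalConstants) -> float:
    """Apparent first-order enzyme-to-site association rate, s⁻¹.

    Smoluchowski encounter rate for two diffusing spheres, scaled by the
    nuclear enzyme concentration::

        k_on = 4π (D_E + D_S)(r_E + r_S) n_E / V_nucleus

    With D_E ≈ 3.8 µm²/s, 2.5 nm radii, 5000 enzymes in 500 µm³ this gives
    the reference value of 2.4 s⁻¹.
    """
    if pc.D_E + pc.D_S < 0:
        raise ValueError("diffusion coefficients must be >= 0")
    return 4.0 * np.pi * (pc.D_E + pc.D_S) * (pc.r_E + pc.r_S) * pc.n_E / pc.V_nucleus


def slide_rate(D_1d: float, d: float) -> float:
    """Nucleosome-to-nucleosome hop rate, s⁻¹, from a 1D diffusion constant.

    The standard 1D random-walk mapping MSD = 2 D t over steps of size d
    gives ``k = 2 D / d²``.  D_1d = 2×10⁻⁴ µm²/s over d = 25 nm yields
    0.64 s⁻¹, quoted as the reference ``k_slide = 0.6``.  The simulator
    treats ``k_slide`` as the *total* hop rate and splits it equally over
    the two directions, preserving the MSD correspondence.
    """
    _require_positive(D_1d=D_1d, d=d)
    return 2.0 * D_1d / d**2


def off_rate_from_residence(residence_time: float) -> float:
    """Dissociation rate, s⁻¹, as the reciprocal mean residence time."""
    _require_positive(residence_time=residence_time)
    return 1.0 / residence_time


def recruitment_efficiency(k_recruitment: float, k_demodification: float) -> float:
    """RE: modification lifetime over mean time before recruitment.

    RE = (1/k_demodification) / (1/k_recruitment) = k_recruitment / k_demodification.
    """
    _require_positive(k_recruitment=k_recruitment, k_demodification=k_demodification)
    return k_recruitment / k_demodification


def k_recruitment_for_re(re: float, k_demodification: float = 2.4) -> float:
    """Recruitment rate realizing a target recruitment efficiency."""
    _require_positive(re=re, k_demodification=k_demodification)
    return re * k_demodification


def table1_report(pc: PhysicalConstants | None = None) -> dict:
    """Regenerate the reference rate constants from physical constants.

    Returns the derived ``k_on``, ``k_off`` and ``k_slide`` together with the
    assumed catalytic rates, as a name -> s⁻¹ mapping.
    """
    pc = pc or PhysicalConstants()
    return {
        "k_on": diffusion_limited_association(pc),
        "k_off": off_rate_from_residence(pc.residence_time),
        "k_slide": slide_rate(pc.D_1d, pc.d_spacing),
        "k_transferase": 1000.0,
        "k_neighbor": 0.2,
        "k_demodification": diffusion_limited_association(pc),
        "k_background_acetylation": diffusion_limited_association(pc),
    }
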