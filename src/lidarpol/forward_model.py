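"""Small-angle vector-RTE forward model of the lidar depolarization ratio.

For an initially linearly polarized pulse, the small-angle solution of the
vector lidar radiative-transfer equation gives the degree of linear
polarization of the return at along-beam range ``z`` as

    g(z) = M22(pi) * exp(-2 * phi * b * z)

where ``M22(pi)`` is the 2,2-element of the normalized scattering matrix of
bulk seawater at 180 degrees (single-scattering depolarization), ``b`` the
total scattering coefficient (1/m), and ``phi`` a dimensionless factor that
sets the exponential growth of depolarization with optical depth ``b*z`` due
to multiple near-forward scattering. The measured linear depolarization ratio
follows as ``delta = (1 - g)/(1 + g)``.

Bulk ``M22(pi)`` and ``phi`` are composed from scattering components
(particles and pure seawater, or acid-labile calcite / acid-stable particles /
seawater): M22 as an average weighted by each component's backscatter at pi,
``w_n = chi_n * b_bn``, and phi as an average weighted by each component's
scattering coefficient ``b_n``.

`phi` depends on the near-forward Mueller matrix and the receiver geometry and
is treated throughout as a free fitting parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "ModelConstants",
    "ComponentOptics",
    "OpticalState",
    "ModelParams",
    "DEFAULT_CONSTANTS",
    "assemble_components",
    "mix_m22",
    "mix_phi",
    "degree_of_linear_polarization",
    "delta_from_g",
    "predict_delta",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed model coefficients.

    chi_* convert hemispherical backscattering to backscatter at pi (sr):
    0.5 sr for all particulate components, 0.68 sr for pure seawater.
    Molecular scattering is non-depolarizing (m22_sw = 1, phi_sw = 0).
    ``m22_labile_fixed`` is the laboratory value for coccolith calcite used by
    the two-particle model. ``b_sw``/``b_bsw`` are fallback pure-seawater
    coefficients at 532 nm used when a dataset carries none of its own.
    """

    chi_p: float = 0.5
    chi_sw: float = 0.68
    chi_labile: float = 0.5
    chi_acid: float = 0.5
    m22_sw: float = 1.0
    phi_sw: float = 0.0
    m22_labile_fixed: float = 0.78
    backscatter_ratio_labile: float = 0.025  # b_b'/b' for coccoliths
    z_default: float = 6.5   # m, along-beam in-water range
    b_sw: float = 1.2e-3     # 1/m
    b_bsw: float = 9.0e-4    # 1/m


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class ComponentOptics:
    """One scattering component's polarization and scattering properties."""

    name: str
    m22: float   # backscatter Mueller element, (0, 1]
    phi: float   # forward-depolarization factor, >= 0
    chi: float   # sr
    b: float     # scattering coefficient, 1/m
    bb: float    # backscattering coefficient, 1/m

    def __post_init__(self) -> None:
        if not 0 < self.m22 <= 1:
            raise ValueError(f"{self.name}: m22 must lie in (0, 1]")
        if self.phi < 0:
            raise ValueError(f"{self.name}: phi must be nonnegative")
        if self.chi <= 0:
            raise ValueError(f"{self.name}: chi must be positive")
        if self.b < 0 or self.bb < 0 or self.bb > self.b:
            raise ValueError(
                f"{self.name}: need 0 <= bb <= b, got b={self.b}, bb={self.bb}"
            )


@dataclass(frozen=True)
class OpticalState:
    """Bulk IOPs and geometry for one field observation.

    ``b_b_labile`` is the acid-labile (calcite) part of ``b_bp``;
    ``backscatter_ratio_labile`` is the assumed backscattering ratio b_b'/b'
    of coccolith calcite used to reconstruct its scattering coefficient.
    """

    b_p: float            # particulate scattering, 1/m
    b_bp: float           # particulate backscattering, 1/m
    b_b_labile: float     # acid-labile backscattering, 1/m
    b_sw: float           # pure-seawater scattering, 1/m
    b_bsw: float          # pure-seawater backscattering, 1/m
    z: float              # along-beam in-water range, m
    backscatter_ratio_labile: float = 0.025

    def __post_init__(self) -> None:
        for name in ("b_p", "b_bp", "b_b_labile", "b_sw", "b_bsw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.b_b_labile > self.b_bp:
            raise ValueError("b_b_labile cannot exceed b_bp")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.backscatter_ratio_labile <= 0:
            raise ValueError("backscatter_ratio_labile must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the single- or two-particle water model.

    single: bulk particulate (m22_p, phi_p).
    two: acid-labile calcite (m22_labile fixed, phi_labile free) plus
    acid-stable particles (m22_acid, phi_acid).

    phi values above 0.4 are allowed (the physical bound used here is 1) but
    lie beyond the range normally explored, so they trigger a warning.
    """

    model_kind: str  # "single" | "two"
    m22_p: Optional[float] = None
    phi_p: Optional[float] = None
    m22_acid: Optional[float] = None
    phi_labile: Optional[float] = None
    phi_acid: Optional[float] = None
    m22_labile: float = 0.78

    def __post_init__(self) -> None:
        if self.model_kind == "single":
            needed = {"m22_p": self.m22_p, "phi_p": self.phi_p}
        elif self.model_kind == "two":
            needed = {
                "m22_acid": self.m22_acid,
                "phi_labile": self.phi_labile,
                "phi_acid": self.phi_acid,
                "m22_labile": self.m22_labile,
            }
        else:
            raise ValueError(f"model_kind must be 'single' or 'two', got "
                             f"{self.model_kind!r}")
        for name, v in needed.items():
            if v is None:
                raise ValueError(f"{self.model_kind} model requires {name}")
            if name.startswith("m22") and not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
            if name.startswith("phi"):
                if not 0 <= v <= 1:
                    raise ValueError(f"{name} must lie in [0, 1]")
                if v > 0.4:
                    warnings.warn(
                        f"{name}={v} exceeds the usually explored range 0-0.4",
                        stacklevel=3,
                    )


# ---------------------------------------------------------------------------
# Component assembly and mixing
# ---------------------------------------------------------------------------

def assemble_components(
    state: OpticalState,
    params: ModelParams,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[ComponentOptics]:
    """Build the list of scattering components for a water model.

    single: particulate + seawater.
    two: acid-labile calcite (its scattering coefficient reconstructed as
    b' = b_b'/backscatter_ratio) + acid-stable (b_p - b', b_bp - b_b') +
    seawater. Inconsistent IOPs (b' > b_p) raise ``ValueError``.
    """
    sw = ComponentOptics(
        "seawater", constants.m22_sw, constants.phi_sw, constants.chi_sw,
        state.b_sw, state.b_bsw,
    )
    if params.model_kind == "single":
        particles = ComponentOptics(
            "particles", params.m22_p, params.phi_p, constants.chi_p,
            state.b_p, state.b_bp,
        )
        return [particles, sw]

    b_labile = state.b_b_labile / state.backscatter_ratio_labile
    if b_labile > state.b_p:
        raise ValueError(
            f"inconsistent IOPs: reconstructed b'={b_labile:g} exceeds "
            f"b_p={state.b_p:g}"
        )
    labile = ComponentOptics(
        "acid-labile", params.m22_labile, params.phi_labile,
        constants.chi_labile, b_labile, state.b_b_labile,
    )
    acid = ComponentOptics(
        "acid-stable", params.m22_acid, params.phi_acid, constants.chi_acid,
        state.b_p - b_labile, state.b_bp - state.b_b_labile,
    )
    return [labile, acid, sw]


def mix_m22(components: Sequence[ComponentOptics]) -> float:
    """Bulk M22(pi) as the chi*bb-weighted average over components.

    Weights are w_n = chi_n * b_bn, i.e. the bulk volume scattering at pi is
    identified with 2*pi*beta(pi) = sum chi_n * b_bn so the combination is a
    normalized (convex) average of the component M22 values.
    """
    weights = [c.chi * c.bb for c in components]
    total = sum(weights)
    if total <= 0:
        raise ValueError("all backscatter weights are zero")
    return sum(c.m22 * w for c, w in zip(components, weights)) / total


def mix_phi(components: Sequence[ComponentOptics]) -> float:
    """Bulk forward-depolarization factor as the b-weighted average."""
    total = sum(c.b for c in components)
    if total <= 0:
        raise ValueError("total scattering coefficient is zero")
    return sum(c.phi * c.b for c in components) / total


# ---------------------------------------------------------------------------
# Radiative transfer chain
# ---------------------------------------------------------------------------

def degree_of_linear_polarization(
    m22: float, phi: float, b: float, z: float
) -> float:
    """g(z) = M22(pi) * exp(-2 * phi * b * z); nonincreasing in phi, b, z."""
    if not 0 < m22 <= 1:
        raise ValueError("m22 must lie in (0, 1]")
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    if b < 0 or z < 0:
        raise ValueError("b and z must be nonnegative")
    return m22 * math.exp(-2.0 * phi * b * z)


def delta_from_g(g: float) -> float:
    """Depolarization ratio delta = (1 - g)/(1 + g) for g in (0, 1]."""
    if not 0 < g <= 1:
        raise ValueError("g must lie in (0, 1]")
    return (1.0 - g) / (1.0 + g)


def predict_delta(
    state: OpticalState,
    params: ModelParams,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Forward-model delta for one observation.

    Assembles components, mixes M22 and phi, evaluates g at the total
    scattering coefficient b = b_p + b_sw and the observation range, and
    converts to delta.
    """
    components = assemble_components(state, params, constants)
    m22 = mix_m22(components)
    phi = mix_phi(components)
    b_total = sum(c.b for c in components)
    g = degree_of_linear_polarization(m22, phi, b_total, state.z)
    return delta_from_g(g)
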