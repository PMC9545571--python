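"""Reduction of benchtop polarized-scattering measurements.

A linearly polarized 532 nm beam illuminates a tank of particle suspension and
a polarization analyzer in front of the detector selects the co- or
cross-polarized component of the near-backward (178.5°) scattered flux.
Particles are spiked into the tank in a serial "standard addition" sequence so
that the concentration independence of the depolarization ratio — i.e., the
absence of multiple scattering — can be verified on the same data that yield
the estimate.

This module turns such a series into the particulate linear depolarization
ratio ``delta_p`` and the backscattering Mueller-matrix element ``M22(pi)``,
partitions ``M22`` into acid-labile (calcite) and acid-stable contributions,
fits a two-component mixing model to particle-mixing additions, and converts
particle shape models to equivalent spherical diameters via Cauchy's
projected-area theorem.

Measurements at 178.5° are treated as exact-backscatter values; no
off-180° correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SignalPair",
    "Addition",
    "StandardAdditionSeries",
    "DepolResult",
    "AcidPartition",
    "MixingAddition",
    "MixingFit",
    "ShapeModel",
    "compute_delta_p",
    "m22_from_delta",
    "delta_from_m22",
    "partition_acid_labile",
    "labile_scattering_fraction",
    "fit_mixing_model",
    "esd_from_shape",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalPair:
    """Co- and cross-polarized detector signals (arbitrary linear units)."""

    co: float
    cross: float

    def __post_init__(self) -> None:
        if self.co < 0 or self.cross < 0:
            raise ValueError(
                f"detector signals must be nonnegative, got co={self.co}, "
                f"cross={self.cross}"
            )


@dataclass(frozen=True)
class Addition:
    """One standard addition: spiked stock volume plus the measured signals."""

    added_volume_mL: float
    signal: SignalPair
    c_spec: Optional[float] = None  # beam attenuation (1/m); plotting scale only

    def __post_init__(self) -> None:
        if self.added_volume_mL <= 0:
            raise ValueError("added_volume_mL must be positive")


@dataclass(frozen=True)
class StandardAdditionSeries:
    """An ordered standard-addition experiment on one particle suspension.

    ``blank`` holds the background-water signals; ``dark_co``/``dark_cross``
    are detector dark readings subtracted from every signal (blank included)
    before the blank subtraction of the depolarization formula.
    """

    blank: SignalPair
    additions: tuple[Addition, ...]
    dark_co: float = 0.0
    dark_cross: float = 0.0
    stock_concentration: Optional[float] = None  # particles/mL
    tank_volume_L: Optional[float] = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "additions", tuple(self.additions))
        if not self.additions:
            raise ValueError("series must contain at least one addition")
        vols = [a.added_volume_mL for a in self.additions]
        if any(b <= a for a, b in zip(vols, vols[1:])):
            raise ValueError("added volumes must be strictly increasing")
        if self.dark_co < 0 or self.dark_cross < 0:
            raise ValueError("dark readings must be nonnegative")


@dataclass(frozen=True)
class DepolResult:
    """Particulate depolarization ratio with its 95% CI and M22(pi)."""

    delta_p: float
    m22: float
    ci95_delta: float
    per_addition_delta: tuple[float, ...]
    n_additions: int


@dataclass(frozen=True)
class AcidPartition:
    """Acid-labile/acid-stable decomposition of a bulk M22(pi).

    The bulk element is the scattered-flux-weighted average of the labile
    (calcite) and stable (post-acidification) elements:
    ``m22_bulk = m22_labile*f + m22_acid*(1 - f)`` with ``f`` the acid-labile
    fraction of the pi-scattered flux.
    """

    m22_bulk: float
    m22_acid: float
    labile_fraction: float
    m22_labile: float

    @classmethod
    def from_measurements(
        cls, m22_bulk: float, m22_acid: float, labile_fraction: float
    ) -> "AcidPartition":
        m22_labile = partition_acid_labile(m22_bulk, m22_acid, labile_fraction)
        return cls(m22_bulk, m22_acid, labile_fraction, m22_labile)


@dataclass(frozen=True)
class MixingAddition:
    """One addition of a second particle suspension into a finished series."""

    added_volume_mL: float
    signal: SignalPair


@dataclass(frozen=True)
class MixingFit:
    """Result of the two-component linear mixing-model fit."""

    m22_added: float
    scale: float  # blank-corrected signal added per mL of the second stock
    m22_base: float
    residual_rms: float


@dataclass(frozen=True)
class ShapeModel:
    """Idealized particle shape: sphere, or circular cylinder (d, h) in um."""

    kind: str  # "sphere" | "cylinder"
    diameter: float
    height: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.kind == "cylinder":
            if self.height is None or self.height <= 0:
                raise ValueError("cylinder requires a positive height")

    @property
    def aspect_ratio(self) -> float:
        """Height:diameter ratio (1 for a sphere)."""
        if self.kind == "sphere":
            return 1.0
        return self.height / self.diameter  # type: ignore[operator]


# ---------------------------------------------------------------------------
# delta <-> M22 algebra
# ---------------------------------------------------------------------------

def m22_from_delta(delta):
    """Backscattering Mueller element M22(pi) = (1 - delta)/(1 + delta).

    Valid for single scattering only; strictly decreasing on ``0 <= delta < 1``.
    Accepts scalars or arrays.
    """
    x = np.asarray(delta, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("delta must lie in [0, 1)")
    out = (1.0 - x) / (1.0 + x)
    return float(out) if np.isscalar(delta) or x.ndim == 0 else out


def delta_from_m22(m22):
    """Linear depolarization ratio delta = (1 - M22)/(1 + M22), M22 in (0, 1]."""
    x = np.asarray(m22, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("m22 must lie in (0, 1]")
    out = (1.0 - x) / (1.0 + x)
    return float(out) if np.isscalar(m22) or x.ndim == 0 else out


# ---------------------------------------------------------------------------
# Standard-addition reduction
# ---------------------------------------------------------------------------

def compute_delta_p(series: StandardAdditionSeries) -> DepolResult:
    """Reduce a standard-addition series to delta_p and M22(pi).

    Darks are subtracted from every signal, then the blank is subtracted from
    each addition; each addition yields
    ``delta_i = (cross_i - cross_blank)/(co_i - co_blank)``.
    ``delta_p`` is the unweighted mean over additions and the CI half-width is
    the two-sided 95% Student-t interval over the per-addition values.

    Additions whose co-polarized excess over the blank is not positive are
    indistinguishable from background and are dropped with a warning; a series
    with no usable addition raises ``ValueError``.
    """
    blank_co = series.blank.co - series.dark_co
    blank_cross = series.blank.cross - series.dark_cross

    deltas: list[float] = []
    for i, add in enumerate(series.additions, start=1):
        den = (add.signal.co - series.dark_co) - blank_co
        num = (add.signal.cross - series.dark_cross) - blank_cross
        if den <= 0:
            warnings.warn(
                f"addition {i} of series {series.sample_id!r}: co-polarized "
                f"excess {den:g} <= 0 (indistinguishable from blank); dropped",
                stacklevel=2,
            )
            continue
        deltas.append(num / den)

    if not deltas:
        raise ValueError(
            f"series {series.sample_id!r}: every addition was indistinguishable "
            "from the blank"
        )

    arr = np.asarray(deltas)
    delta_p = float(arr.mean())
    if arr.size >= 2:
        sem = arr.std(ddof=1) / math.sqrt(arr.size)
        ci95 = float(stats.t.ppf(0.975, arr.size - 1) * sem)
    else:
        warnings.warn("single usable addition: 95% CI undefined", stacklevel=2)
        ci95 = float("nan")

    return DepolResult(
        delta_p=delta_p,
        m22=m22_from_delta(delta_p),
        ci95_delta=ci95,
        per_addition_delta=tuple(deltas),
        n_additions=len(deltas),
    )


# ---------------------------------------------------------------------------
# Acid-labile partitioning
# ---------------------------------------------------------------------------

def partition_acid_labile(
    m22_bulk: float, m22_acid: float, labile_fraction: float
) -> float:
    """Solve the acid-labile Mueller element from the linear flux partition.

    The bulk M22(pi) is assumed to be the pi-scattered-flux-weighted average of
    acid-labile and acid-stable contributions, so

        m22_labile = (m22_bulk - m22_acid * (1 - f)) / f

    with ``f`` the acid-labile scattering fraction. A result outside (0, 1]
    signals inconsistent inputs and is returned as computed with a warning.
    """
    if not 0 < labile_fraction <= 1:
        raise ValueError("labile_fraction must lie in (0, 1]")
    for name, v in (("m22_bulk", m22_bulk), ("m22_acid", m22_acid)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    m22_labile = (m22_bulk - m22_acid * (1.0 - labile_fraction)) / labile_fraction
    if not 0 < m22_labile <= 1:
        warnings.warn(
            f"partitioned m22_labile={m22_labile:.4f} falls outside (0, 1]; "
            "the bulk/acid/fraction inputs are mutually inconsistent",
            stacklevel=2,
        )
    return m22_labile


def labile_scattering_fraction(slope_bulk: float, slope_acid: float) -> float:
    """Fraction of pi-scattered flux contributed by acid-labile particles.

    Computed from the slopes of return signal vs. stock concentration before
    and after acidification: ``1 - slope_acid/slope_bulk``. Acidification
    dissolves calcite and can only remove scattering, so the acidified slope
    may not exceed the bulk slope.
    """
    if slope_acid <= 0:
        raise ValueError("slope_acid must be positive")
    if slope_acid > slope_bulk:
        raise ValueError(
            "slope_acid exceeds slope_bulk: acidification cannot add scattering"
        )
    return 1.0 - slope_acid / slope_bulk


# ---------------------------------------------------------------------------
# Particle-mixing model
# ---------------------------------------------------------------------------

def fit_mixing_model(
    base_signal: SignalPair,
    mixing_additions: Sequence[MixingAddition],
) -> MixingFit:
    """Estimate M22(pi) of a second suspension mixed into a finished series.

    The bulk element after adding volume ``v`` of the second stock follows the
    signal-weighted two-component average

        M22(v) = (w0 * M22_base + k * v * M22_add) / (w0 + k * v)

    where ``w0 = co + cross`` of the (blank-corrected) base suspension,
    ``M22_base`` comes from the base signal ratio, and ``k`` is the
    blank-corrected signal added per mL of stock. ``(M22_add, k)`` are fit by
    nonlinear least squares to the observed per-addition bulk M22 values;
    ``M22_add`` is initialized at the last observed bulk value (the mixing
    curve approaches it asymptotically) and ``k`` from the first addition's
    total-signal increment.

    Signals are expected dark- and blank-corrected. When the added suspension
    matches the base (all observed M22 equal), ``k`` is unidentifiable and the
    fit returns ``M22_base`` without error.
    """
    if len(mixing_additions) < 3:
        raise ValueError("need at least 3 mixing additions")
    vols = np.array([a.added_volume_mL for a in mixing_additions], dtype=float)
    if np.any(np.diff(vols) <= 0):
        raise ValueError("mixing added volumes must be strictly increasing")
    if base_signal.co <= 0:
        raise ValueError("base co-polarized signal must be positive")

    w0 = base_signal.co + base_signal.cross
    m22_base = m22_from_delta(base_signal.cross / base_signal.co)

    m22_obs = np.empty_like(vols)
    totals = np.empty_like(vols)
    for i, a in enumerate(mixing_additions):
        if a.signal.co <= 0:
            raise ValueError(f"mixing addition {i + 1}: co signal must be positive")
        m22_obs[i] = m22_from_delta(a.signal.cross / a.signal.co)
        totals[i] = a.signal.co + a.signal.cross

    def model(theta: np.ndarray) -> np.ndarray:
        m22_add, k = theta
        kv = k * vols
        return (w0 * m22_base + kv * m22_add) / (w0 + kv)

    k0 = (totals[0] - w0) / vols[0]
    if not np.isfinite(k0) or k0 <= 0:
        k0 = w0 / vols[-1]
    x0 = np.array([m22_obs[-1], k0])
    # M22_add bounded above at 2, not 1, so that inconsistent data produce a
    # warning instead of being silently clipped to the physical limit.
    res = optimize.least_squares(
        lambda th: model(th) - m22_obs,
        x0,
        bounds=([1e-9, 0.0], [2.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"mixing-model fit failed: {res.message}; residuals {res.fun!r}"
        )
    m22_added, scale = map(float, res.x)
    if not 0 < m22_added <= 1:
        warnings.warn(
            f"fitted M22_add={m22_added:.4f} outside (0, 1]", stacklevel=2
        )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return MixingFit(m22_added=m22_added, scale=scale, m22_base=m22_base,
                     residual_rms=rms)


# ---------------------------------------------------------------------------
# Equivalent spherical diameter
# ---------------------------------------------------------------------------

def esd_from_shape(shape: ShapeModel) -> float:
    """Equivalent spherical diameter from mean projected area (Cauchy).

    For a convex body the orientation-averaged projected area is one quarter
    of the surface area; the ESD is the diameter of the sphere with that
    projected area, ``2*sqrt(A/pi)``. A sphere maps to its own diameter; a
    cylinder (d, h) has surface ``pi*d*h + pi*d^2/2`` so
    ``ESD = sqrt(d*h + d^2/2)``, continuous down to the disk limit h -> 0.
    """
    if shape.kind == "sphere":
        return shape.diameter
    d, h = shape.diameter, shape.height
    area = (math.pi * d * h + math.pi * d * d / 2.0) / 4.0
    return 2.0 * math.sqrt(area / math.pi)
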