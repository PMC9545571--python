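"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data the pipeline consumes:

* :func:`generate_lab_series` — a benchtop standard-addition experiment in
  which the blank-corrected co-polarized signal grows linearly with the number
  of additions and the cross-polarized signal is a fixed fraction
  (``true_delta``) of it, with multiplicative Gaussian noise. Per-addition
  delta is concentration-independent by construction, i.e. the simulated
  measurement is free of multiple scattering.
* :func:`generate_mixing_series` — particle-mixing additions following the
  signal-weighted two-component mixing law, for exercising the mixing-model
  fit.
* :func:`generate_field_observations` — an underway IOP + lidar-delta time
  series: particulate scattering drawn log-uniformly across a
  bloom-to-coastal range, backscattering ratios and acid-labile (calcite)
  fractions drawn uniformly, and observed delta computed from a known forward
  model truth plus truncated Gaussian noise.

All generators are pure functions of their config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward_model import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    ModelParams,
    OpticalState,
    predict_delta,
)
from .lab_reduction import (
    Addition,
    MixingAddition,
    SignalPair,
    StandardAdditionSeries,
    delta_from_m22,
)

__all__ = [
    "LabSimConfig",
    "FieldSimConfig",
    "generate_lab_series",
    "generate_mixing_series",
    "generate_field_observations",
]


@dataclass(frozen=True)
class LabSimConfig:
    """Configuration for a simulated standard-addition series.

    ``noise_sd`` is the relative (fractional) standard deviation of the
    multiplicative noise applied independently to the co- and cross-polarized
    blank-corrected excess of each addition. Signal units are arbitrary
    (detector mV); the defaults give a blank well below the particle signal,
    as in a filtered-water background.
    """

    true_delta: float
    n_additions: int = 6
    blank_co: float = 50.0
    blank_cross: float = 5.0
    signal_per_addition: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0
    dark_co: float = 2.0
    dark_cross: float = 1.0
    volume_per_addition_mL: float = 5.0
    stock_concentration: float = 3.6e7  # particles/mL
    tank_volume_L: float = 23.0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.true_delta < 1:
            raise ValueError("true_delta must lie in [0, 1)")
        if self.n_additions < 3:
            raise ValueError("n_additions must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.signal_per_addition <= 0:
            raise ValueError("signal_per_addition must be positive")


def generate_lab_series(config: LabSimConfig) -> StandardAdditionSeries:
    """Simulate a standard-addition series with known true delta.

    Addition ``i`` (1-based) records

        co_i    = dark_co    + blank_co    + i * s * (1 + eps_i)
        cross_i = dark_cross + blank_cross + i * s * true_delta * (1 + eps'_i)

    with ``s = signal_per_addition`` and eps, eps' ~ N(0, noise_sd). With
    ``noise_sd = 0`` the reduction recovers ``true_delta`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.noise_sd or 0.0, size=(config.n_additions, 2))
    if config.noise_sd == 0.0:
        eps[:] = 0.0

    blank = SignalPair(
        co=config.dark_co + config.blank_co,
        cross=config.dark_cross + config.blank_cross,
    )
    additions = []
    for i in range(1, config.n_additions + 1):
        excess_co = i * config.signal_per_addition * (1.0 + eps[i - 1, 0])
        excess_cross = (i * config.signal_per_addition * config.true_delta
                        * (1.0 + eps[i - 1, 1]))
        additions.append(
            Addition(
                added_volume_mL=i * config.volume_per_addition_mL,
                signal=SignalPair(
                    co=config.dark_co + config.blank_co + excess_co,
                    cross=config.dark_cross + config.blank_cross + excess_cross,
                ),
            )
        )
    return StandardAdditionSeries(
        blank=blank,
        additions=tuple(additions),
        dark_co=config.dark_co,
        dark_cross=config.dark_cross,
        stock_concentration=config.stock_concentration,
        tank_volume_L=config.tank_volume_L,
        sample_id=config.sample_id,
    )


def generate_mixing_series(
    base_m22: float,
    added_m22: float,
    base_weight: float,
    added_weights: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SignalPair, list[MixingAddition]]:
    """Simulate particle-mixing additions under the two-component mixing law.

    ``base_weight`` is the total blank-corrected signal (co + cross) of the
    base suspension and each entry of ``added_weights`` the signal contributed
    by the added suspension at that addition (the generator uses a stock
    strength of one signal unit per mL, so added volumes equal the weights).
    Bulk M22 at addition i follows

        M22_i = (w0 * base_m22 + a_i * added_m22) / (w0 + a_i)

    optionally perturbed by additive Gaussian noise before conversion back to
    co/cross signal pairs. Returns the base signal pair and the additions,
    ready for :func:`lidarpol.lab_reduction.fit_mixing_model`.
    """
    for name, v in (("base_m22", base_m22), ("added_m22", added_m22)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1]")
    if base_weight <= 0:
        raise ValueError("base_weight must be positive")
    weights = np.asarray(list(added_weights), dtype=float)
    if weights.size == 0 or np.any(weights < 0):
        raise ValueError("added_weights must be nonnegative and nonempty")

    rng = np.random.default_rng(seed)
    delta_base = delta_from_m22(base_m22)
    base_signal = SignalPair(
        co=base_weight / (1.0 + delta_base),
        cross=base_weight * delta_base / (1.0 + delta_base),
    )
    additions = []
    for i, a in enumerate(weights):
        m22_i = (base_weight * base_m22 + a * added_m22) / (base_weight + a)
        if noise_sd > 0:
            m22_i += rng.normal(0.0, noise_sd)
        m22_i = float(np.clip(m22_i, 1e-9, 1.0))
        delta_i = delta_from_m22(m22_i)
        total = base_weight + a
        additions.append(
            MixingAddition(
                added_volume_mL=float(a) if a > 0 else 1e-9 * (i + 1),
                signal=SignalPair(
                    co=total / (1.0 + delta_i),
                    cross=total * delta_i / (1.0 + delta_i),
                ),
            )
        )
    return base_signal, additions


@dataclass(frozen=True)
class FieldSimConfig:
    """Configuration for a simulated underway IOP + delta time series.

    Default ranges loosely emulate a coccolithophore-bloom-to-coastal
    transect: particulate scattering ``b_p`` log-uniform in [0.05, 1.5] 1/m,
    backscattering ratio ``b_bp/b_p`` uniform in [0.005, 0.03], acid-labile
    backscattering fraction ``b_b'/b_bp`` uniform in [0, 0.8]. Draws whose
    reconstructed calcite scattering b' = b_b'/0.025 would exceed b_p are
    resampled so every generated row satisfies the model's IOP constraints.
    """

    n_obs: int
    truth: ModelParams
    b_p_range: tuple[float, float] = (0.05, 1.5)
    bbp_over_bp_range: tuple[float, float] = (0.005, 0.03)
    labile_fraction_range: tuple[float, float] = (0.0, 0.8)
    b_sw: float = DEFAULT_CONSTANTS.b_sw
    b_bsw: float = DEFAULT_CONSTANTS.b_bsw
    z: float = DEFAULT_CONSTANTS.z_default
    delta_noise_sd: float = 0.0
    seed: int = 0
    backscatter_ratio_labile: float = DEFAULT_CONSTANTS.backscatter_ratio_labile

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be positive")
        for name in ("b_p_range", "bbp_over_bp_range", "labile_fraction_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and nonnegative")
        if self.b_p_range[0] <= 0:
            raise ValueError("b_p_range lower bound must be positive")
        if self.labile_fraction_range[1] > 1:
            raise ValueError("labile fractions must lie in [0, 1]")
        if self.delta_noise_sd < 0:
            raise ValueError("delta_noise_sd must be nonnegative")


def generate_field_observations(
    config: FieldSimConfig,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[tuple[OpticalState, float]]:
    """Simulate field observations from a known forward-model truth.

    Each row draws IOPs per :class:`FieldSimConfig`, evaluates the forward
    model at the true parameters, and adds Gaussian noise truncated to
    [0, 1) by resampling. The result is reproducible: same config, same rows.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.b_p_range

    # Infeasible config guard: even the smallest possible labile draw must be
    # reconcilable with b' <= b_p.
    min_bbp, _ = config.bbp_over_bp_range
    min_frac, _ = config.labile_fraction_range
    if min_bbp * min_frac / config.backscatter_ratio_labile > 1:
        raise ValueError(
            "labile_fraction_range/backscatter ratio make every draw violate "
            "b' <= b_p"
        )

    observations: list[tuple[OpticalState, float]] = []
    max_resample = 10_000
    for _ in range(config.n_obs):
        for attempt in range(max_resample):
            b_p = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            b_bp = b_p * float(rng.uniform(*config.bbp_over_bp_range))
            b_bl = b_bp * float(rng.uniform(*config.labile_fraction_range))
            if b_bl / config.backscatter_ratio_labile <= b_p:
                break
        else:
            raise RuntimeError(
                "could not draw IOPs satisfying b' <= b_p after "
                f"{max_resample} attempts"
            )
        state = OpticalState(
            b_p=b_p, b_bp=b_bp, b_b_labile=b_bl,
            b_sw=config.b_sw, b_bsw=config.b_bsw, z=config.z,
            backscatter_ratio_labile=config.backscatter_ratio_labile,
        )
        delta = predict_delta(state, config.truth, constants)
        if config.delta_noise_sd > 0:
            for _ in range(max_resample):
                candidate = delta + float(rng.normal(0.0, config.delta_noise_sd))
                if 0.0 <= candidate < 1.0:
                    delta = candidate
                    break
            else:  # pragma: no cover - would need absurd noise levels
                raise RuntimeError("could not draw delta noise within [0, 1)")
        observations.append((state, delta))
    return observations
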