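"""Grid-search inversion of the forward depolarization model.

The free parameters of the single-particle model (M22_p, phi_p) or the
two-particle model (M22_acid, phi_labile, phi_acid) are fit to an observed
delta time series by exhaustive evaluation of the forward model on a regular
parameter grid, scored with a degrees-of-freedom-corrected RMSE

    RMSE = sqrt( sum_i (delta_i - delta_hat_i)^2 / (N - k) )

with ``k`` the number of explanatory coefficients. The full RMSE surface is
retained so that the compensation structure between single-scattering
(M22) and multiple-scattering (phi) depolarization — iso-RMSE ridges — can be
profiled.

The grid evaluation is vectorized over observations and grid nodes but uses
exactly the component-mixing formulas of :mod:`lidarpol.forward_model`; tests
cross-check surface values against per-node re-evaluation through the scalar
``predict_delta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .forward_model import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    ModelParams,
    OpticalState,
)

__all__ = [
    "AxisSpec",
    "GridSpec",
    "GridResult",
    "rmse",
    "grid_search",
    "ridge_profile",
    "compare_models",
]

_AXES_BY_KIND = {
    "single": ("m22_p", "phi_p"),
    "two": ("m22_acid", "phi_labile", "phi_acid"),
}


@dataclass(frozen=True)
class AxisSpec:
    """One grid axis: inclusive [start, stop] walked in uniform steps."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    def values(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for one model kind.

    ``axes`` maps parameter name to :class:`AxisSpec`, in a fixed order that
    also defines the surface array layout. ``k`` is the explanatory-coefficient
    count of the RMSE denominator; it defaults to the number of free
    parameters (2 single, 3 two-particle).
    """

    model_kind: str
    axes: Mapping[str, AxisSpec]
    k: int | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in _AXES_BY_KIND:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        expected = _AXES_BY_KIND[self.model_kind]
        if tuple(self.axes) != expected:
            raise ValueError(
                f"{self.model_kind} grid must have axes {expected}, "
                f"got {tuple(self.axes)}"
            )
        object.__setattr__(self, "axes", dict(self.axes))

    @property
    def n_free(self) -> int:
        return len(self.axes)

    @property
    def k_effective(self) -> int:
        return self.n_free if self.k is None else self.k

    def axis_values(self) -> dict[str, np.ndarray]:
        return {name: ax.values() for name, ax in self.axes.items()}

    @classmethod
    def single(cls, m22=(0.5, 1.0, 0.01), phi=(0.0, 0.4, 0.005),
               k: int | None = None) -> "GridSpec":
        """Default single-particle grid: M22_p 0.5-1, phi_p 0-0.4."""
        return cls("single", {"m22_p": AxisSpec(*m22), "phi_p": AxisSpec(*phi)},
                   k=k)

    @classmethod
    def two(cls, m22=(0.5, 1.0, 0.01), phi_labile=(0.0, 0.4, 0.005),
            phi_acid=(0.0, 0.4, 0.005), k: int | None = None) -> "GridSpec":
        """Default two-particle grid: M22_acid 0.5-1, both phi 0-0.4."""
        return cls(
            "two",
            {
                "m22_acid": AxisSpec(*m22),
                "phi_labile": AxisSpec(*phi_labile),
                "phi_acid": AxisSpec(*phi_acid),
            },
            k=k,
        )


@dataclass(frozen=True)
class GridResult:
    """RMSE surface over a parameter grid and its (tie-broken) optimum."""

    model_kind: str
    axis_names: tuple[str, ...]
    axis_values: tuple[np.ndarray, ...]
    rmse_surface: np.ndarray   # shape = tuple(len(v) for v in axis_values)
    optimum: ModelParams
    optimum_rmse: float
    optimum_index: tuple[int, ...]
    n_obs: int
    k: int

    def axes(self) -> dict[str, np.ndarray]:
        return dict(zip(self.axis_names, self.axis_values))


def rmse(predicted, observed, k: int) -> float:
    """Degrees-of-freedom-corrected root-mean-square error.

    ``sqrt(sum((obs - pred)^2) / (N - k))``; requires N > k.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    n = pred.size
    if n <= k:
        raise ValueError(f"need N > k, got N={n}, k={k}")
    return float(np.sqrt(np.sum((pred - obs) ** 2) / (n - k)))


# ---------------------------------------------------------------------------
# Observation arrays and the vectorized forward kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ObsArrays:
    b_p: np.ndarray
    b_bp: np.ndarray
    b_b_labile: np.ndarray
    b_sw: np.ndarray
    b_bsw: np.ndarray
    z: np.ndarray
    ratio: np.ndarray
    delta_obs: np.ndarray

    @classmethod
    def from_observations(
        cls, observations: Sequence[tuple[OpticalState, float]]
    ) -> "_ObsArrays":
        if not observations:
            raise ValueError("observations must be nonempty")
        states = [s for s, _ in observations]
        return cls(
            b_p=np.array([s.b_p for s in states]),
            b_bp=np.array([s.b_bp for s in states]),
            b_b_labile=np.array([s.b_b_labile for s in states]),
            b_sw=np.array([s.b_sw for s in states]),
            b_bsw=np.array([s.b_bsw for s in states]),
            z=np.array([s.z for s in states]),
            ratio=np.array([s.backscatter_ratio_labile for s in states]),
            delta_obs=np.array([float(d) for _, d in observations]),
        )


def _surface_single(
    obs: _ObsArrays, m22v: np.ndarray, phiv: np.ndarray,
    c: ModelConstants, k: int,
) -> np.ndarray:
    w_p = c.chi_p * obs.b_bp
    w_sw = c.chi_sw * obs.b_bsw
    w_total = w_p + w_sw
    if np.any(w_total <= 0):
        bad = int(np.argmax(w_total <= 0))
        raise ValueError(f"observation {bad}: all backscatter weights are zero")
    b = obs.b_p + obs.b_sw
    bz = b * obs.z
    m22_mix = (np.outer(m22v, w_p) + c.m22_sw * w_sw) / w_total      # (M, N)
    phi_mix = np.outer(phiv, obs.b_p / b) + c.phi_sw * (obs.b_sw / b)  # (P, N)
    decay = np.exp(-2.0 * phi_mix * bz)                               # (P, N)
    g = m22_mix[:, None, :] * decay[None, :, :]                       # (M, P, N)
    delta = (1.0 - g) / (1.0 + g)
    sq = (delta - obs.delta_obs) ** 2
    n = obs.delta_obs.size
    return np.sqrt(sq.sum(axis=-1) / (n - k))


def _surface_two(
    obs: _ObsArrays, m22v: np.ndarray, plv: np.ndarray, pav: np.ndarray,
    c: ModelConstants, k: int,
) -> np.ndarray:
    b_labile = obs.b_b_labile / obs.ratio
    if np.any(b_labile > obs.b_p):
        bad = int(np.argmax(b_labile > obs.b_p))
        raise ValueError(
            f"observation {bad}: reconstructed b' exceeds b_p (inconsistent IOPs)"
        )
    w_lab = c.chi_labile * obs.b_b_labile
    w_acid = c.chi_acid * (obs.b_bp - obs.b_b_labile)
    w_sw = c.chi_sw * obs.b_bsw
    w_total = w_lab + w_acid + w_sw
    if np.any(w_total <= 0):
        bad = int(np.argmax(w_total <= 0))
        raise ValueError(f"observation {bad}: all backscatter weights are zero")
    b = obs.b_p + obs.b_sw
    bz = b * obs.z
    m22_mix = (c.m22_labile_fixed * w_lab + np.outer(m22v, w_acid)
               + c.m22_sw * w_sw) / w_total                           # (M, N)
    phi_mix = (plv[:, None, None] * (b_labile / b)
               + pav[None, :, None] * ((obs.b_p - b_labile) / b)
               + c.phi_sw * (obs.b_sw / b))                           # (PL, PA, N)
    decay = np.exp(-2.0 * phi_mix * bz)
    n = obs.delta_obs.size
    surface = np.empty((m22v.size, plv.size, pav.size))
    for i in range(m22v.size):  # chunked over M to bound memory
        g = m22_mix[i] * decay
        delta = (1.0 - g) / (1.0 + g)
        surface[i] = np.sqrt(((delta - obs.delta_obs) ** 2).sum(-1) / (n - k))
    return surface


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def _params_from_node(
    model_kind: str, node: Mapping[str, float], constants: ModelConstants
) -> ModelParams:
    if model_kind == "single":
        return ModelParams("single", m22_p=float(node["m22_p"]),
                           phi_p=float(node["phi_p"]))
    return ModelParams(
        "two",
        m22_acid=float(node["m22_acid"]),
        phi_labile=float(node["phi_labile"]),
        phi_acid=float(node["phi_acid"]),
        m22_labile=constants.m22_labile_fixed,
    )


def _tie_break(
    candidates: np.ndarray,
    axis_names: Sequence[str],
    axis_values: Sequence[np.ndarray],
) -> tuple[int, ...]:
    """Pick one node among equal-RMSE candidates: smallest phi, then largest M22.

    phi axes are compared first (ascending, in axis order), then M22 axes
    descending, so flat ridges resolve to a deterministic optimum.
    """
    def key(idx: np.ndarray):
        phis = tuple(axis_values[i][idx[i]]
                     for i, n in enumerate(axis_names) if n.startswith("phi"))
        m22s = tuple(-axis_values[i][idx[i]]
                     for i, n in enumerate(axis_names) if n.startswith("m22"))
        return phis + m22s

    best = min(candidates, key=key)
    return tuple(int(i) for i in best)


def grid_search(
    observations: Sequence[tuple[OpticalState, float]],
    grid: GridSpec,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> GridResult:
    """Exhaustively score the forward model on a parameter grid.

    Evaluates the model delta for every grid node and observation, computes
    the Eq.-style RMSE per node, and returns the full surface with the
    arg-min. Exact RMSE ties are broken deterministically (smallest phi, then
    largest M22). The same inputs always yield a bit-identical surface.
    """
    obs = _ObsArrays.from_observations(observations)
    k = grid.k_effective
    if obs.delta_obs.size <= k:
        raise ValueError(
            f"need more observations ({obs.delta_obs.size}) than explanatory "
            f"coefficients (k={k})"
        )
    axes = grid.axis_values()
    if grid.model_kind == "single":
        surface = _surface_single(obs, axes["m22_p"], axes["phi_p"],
                                  constants, k)
    else:
        surface = _surface_two(obs, axes["m22_acid"], axes["phi_labile"],
                               axes["phi_acid"], constants, k)

    names = tuple(axes)
    values = tuple(axes[n] for n in names)
    candidates = np.argwhere(surface == surface.min())
    best = _tie_break(candidates, names, values)
    node = {n: values[i][best[i]] for i, n in enumerate(names)}
    optimum = _params_from_node(grid.model_kind, node, constants)
    return GridResult(
        model_kind=grid.model_kind,
        axis_names=names,
        axis_values=values,
        rmse_surface=surface,
        optimum=optimum,
        optimum_rmse=float(surface[best]),
        optimum_index=best,
        n_obs=int(obs.delta_obs.size),
        k=k,
    )


def ridge_profile(result: GridResult, axis: str) -> list[dict]:
    """Conditional optima along one grid axis.

    For each value of the named axis, returns the arg-min of the RMSE surface
    over the remaining axes (same tie-break as the global optimum). Useful for
    characterizing compensation ridges, e.g. how the conditional optimum of
    M22 falls as phi rises.
    """
    if axis not in result.axis_names:
        raise ValueError(
            f"unknown axis {axis!r}; grid axes are {result.axis_names}"
        )
    pos = result.axis_names.index(axis)
    other_names = tuple(n for i, n in enumerate(result.axis_names) if i != pos)
    other_values = tuple(v for i, v in enumerate(result.axis_values) if i != pos)
    profile = []
    for j, fixed in enumerate(result.axis_values[pos]):
        sub = np.take(result.rmse_surface, j, axis=pos)
        if sub.ndim == 0:  # single-axis grid: profile is the surface itself
            best: tuple[int, ...] = ()
        else:
            cands = np.argwhere(sub == sub.min())
            best = _tie_break(cands, other_names, other_values)
        node = {axis: float(fixed)}
        node.update({n: float(other_values[i][best[i]])
                     for i, n in enumerate(other_names)})
        entry_rmse = float(sub[best]) if best else float(sub)
        profile.append(
            {"fixed_value": float(fixed), "conditional_optimum": node,
             "rmse": entry_rmse}
        )
    return profile


def compare_models(single: GridResult, two: GridResult) -> dict:
    """Compare optimum RMSEs of single- and two-particle fits.

    ``delta_rmse`` is single minus two (positive when the two-particle model
    improves); both fits must cover the same observations.
    """
    if single.model_kind != "single" or two.model_kind != "two":
        raise ValueError("expected a single-particle and a two-particle result")
    if single.n_obs != two.n_obs:
        raise ValueError(
            f"results fitted on different observation counts "
            f"({single.n_obs} vs {two.n_obs})"
        )
    delta = single.optimum_rmse - two.optimum_rmse
    return {
        "rmse_single": single.optimum_rmse,
        "rmse_two": two.optimum_rmse,
        "delta_rmse": delta,
        "improved": two.optimum_rmse < single.optimum_rmse,
    }
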