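"""Trigonometric trajectory simulator with ground-truth progression.

Linear-trajectory inference is hard to validate on real data because the
true cell ordering is unknown.  These generators sample points along 2-D
and 3-D parametric curves — spirals, quadratically growing spirals and a
sine wave — at t-increments of 0.01 and add i.i.d. Gaussian noise to each
coordinate.  The parameter t is carried along as (approximate, once noise
is added) ground truth.  Spirals are the interesting family: they defeat
principal-curve methods initialised from a straight line, while a correct
ordering is still well defined.

Curve families (t in [0, t_max), default extents chosen so each dataset
holds 1157-1785 points and the curve extent is large relative to the
noise sweep 0.05-0.95):

=====================  =============================================  ======
kind                   f(t)                                           t_max
=====================  =============================================  ======
spiral2d               (t cos t, t sin t)                             12.57
spiral2d_quadratic     ((t^2/8) cos t, (t^2/8) sin t)                 12.57
spiral3d               (4 cos t, 4 sin t, 0.4 t)                      17.85
spiral3d_quadratic     ((t^2/8) cos t, (t^2/8) sin t, 0.4 t)          12.57
sine                   (t, 2 sin t)                                   12.57
=====================  =============================================  ======
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_rng
from .errors import InvalidParameterError

__all__ = ["TrajectoryDataset", "simulate_trajectory", "simulate_suite", "KINDS"]

_T_STEP = 0.01

_CURVES = {
    "spiral2d": (lambda t: np.column_stack([t * np.cos(t), t * np.sin(t)]), 12.57),
    "spiral2d_quadratic": (
        lambda t: np.column_stack([(t**2 / 8) * np.cos(t), (t**2 / 8) * np.sin(t)]),
        12.57,
    ),
    "spiral3d": (
        lambda t: np.column_stack([4 * np.cos(t), 4 * np.sin(t), 0.4 * t]),
        17.85,
    ),
    "spiral3d_quadratic": (
        lambda t: np.column_stack(
            [(t**2 / 8) * np.cos(t), (t**2 / 8) * np.sin(t), 0.4 * t]
        ),
        12.57,
    ),
    "sine": (lambda t: np.column_stack([t, 2 * np.sin(t)]), 12.57),
}

KINDS = tuple(_CURVES)

NOISE_LEVELS = tuple(np.round(np.arange(0.05, 1.0, 0.10), 2))  # 0.05 .. 0.95


@dataclass(frozen=True)
class TrajectoryDataset:
    """Simulated coordinates plus the ground-truth parameter t."""

    coords: np.ndarray
    t: np.ndarray
    kind: str
    noise_sd: float

    @property
    def n(self) -> int:
        return self.t.size


def curve_points(kind: str, t: np.ndarray) -> np.ndarray:
    """Noiseless curve coordinates f_kind(t)."""
    if kind not in _CURVES:
        raise InvalidParameterError(f"unknown kind {kind!r}; choose from {KINDS}")
    return _CURVES[kind][0](np.asarray(t, dtype=float))


def simulate_trajectory(
    kind: str,
    t_max: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TrajectoryDataset:
    """Sample a trajectory at t = 0, 0.01, ..., < t_max with Gaussian noise.

    ``noise_sd`` is the per-coordinate standard deviation; 0 gives points
    exactly on the curve.  ``t_max`` defaults to the family value above.
    """
    if kind not in _CURVES:
        raise InvalidParameterError(f"unknown kind {kind!r}; choose from {KINDS}")
    fn, default_tmax = _CURVES[kind]
    t_max = default_tmax if t_max is None else float(t_max)
    if t_max <= 0:
        raise InvalidParameterError(f"t_max must be positive, got {t_max}")
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    n = int(np.ceil(round(t_max / _T_STEP, 9)))
    t = np.arange(n) * _T_STEP
    coords = fn(t)
    if noise_sd > 0:
        rng = derive_rng(seed, "simulate")
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    return TrajectoryDataset(coords=coords, t=t, kind=kind, noise_sd=float(noise_sd))


def simulate_suite(seed: int = 0) -> list[TrajectoryDataset]:
    """The 50-dataset evaluation suite: 5 curve families x 10 noise levels.

    Noise standard deviations run 0.05, 0.15, ..., 0.95; every dataset
    draws noise from an independent sub-seed of ``seed``.
    """
    datasets = []
    i = 0
    for kind in KINDS:
        for sd in NOISE_LEVELS:
            sub = int(
                np.random.SeedSequence(int(seed), spawn_key=(3, i)).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            datasets.append(simulate_trajectory(kind, noise_sd=float(sd), seed=sub))
            i += 1
    return datasets
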