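"""Orbit geometry of ear motions and the conditions for good detection.

Each ear's motion traces a closed *orbit* ``(psi(t), phi(t), theta(t))`` in
roll-pitch-yaw angle space.  Motions are classified by the affine dimension
of each orbit and of the convex hull of the union of both orbits, and by
whether the left/right yaw (resp. pitch) angle functions coincide.  Four
conditions characterise the motions that allow precise *and* robust
direction detection from the ILD signal:

1. the convex hull of the union of the two orbits is three-dimensional;
2. neither orbit degenerates to one dimension (orbit dimension >= 2);
3. the left and right yaw angle functions do not coincide;
4. the left and right pitch angle functions do not coincide.

Within the 0th+1st Fourier-mode family the orbits are points, segments or
planar closed curves, so the hull dimension equals the affine rank of the
pooled orbit samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import (
    DEFAULT_AMPLITUDE,
    DEFAULT_FREQUENCY,
    AngleFunctionPair,
    EarMotion,
    Pairing,
)

__all__ = [
    "OrbitClassification",
    "orbit_points",
    "affine_dimension",
    "classify_motion",
    "satisfies_four_conditions",
    "is_mirror_symmetric",
    "phase_shifted_motion",
    "enumerate_motions",
    "classification_table",
]


@dataclass(frozen=True)
class OrbitClassification:
    """Dimension pair and condition flags of one ear motion."""

    motion: EarMotion
    hull_dim: int
    orbit_dims: tuple[int, int]  #: (left, right)
    conditions: tuple[bool, bool, bool, bool]
    mirror_symmetric: bool

    @property
    def dimension_pair(self) -> str:
        """Label like ``"3-2"`` (hull dimension - orbit dimension)."""
        return f"{self.hull_dim}-{max(self.orbit_dims)}"

    @property
    def satisfies_all(self) -> bool:
        return all(self.conditions)


def orbit_points(motion: EarMotion, side: str, n_samples: int = 256) -> np.ndarray:
    """Samples of one ear's (psi, phi, theta) orbit over a full period.

    Returns an ``(n_samples, 3)`` array in degrees.
    """
    if n_samples < 16:
        raise ValueError("need at least 16 samples to resolve the orbit")
    ts = np.linspace(0.0, motion.period, n_samples, endpoint=False)
    psi, phi, theta = motion.angles(side, ts)
    return np.stack([psi, phi, theta], axis=1)


def affine_dimension(points: np.ndarray, tol: float = 1e-8) -> int:
    """Dimension of the affine span of a point set (0 for a single point).

    Computed as the rank of the centred points via singular values
    thresholded relative to the largest one; an all-zero spread gives 0.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise ValueError("empty point set")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv.size == 0 or sv[0] <= tol:
        return 0
    return int(np.sum(sv > tol * sv[0]))


def is_mirror_symmetric(
    motion: EarMotion, tol: float = 1e-9, n_samples: int = 128
) -> bool:
    """Whether the motion is mirror-symmetric about the midsagittal plane.

    The left ear's motion must equal the half-period-shifted, sagittally
    reflected right ear's motion:

        psi_l(t + T/2) = -psi_r(t),
        phi_l(t + T/2) = +phi_r(t),
        theta_l(t + T/2) = -theta_r(t).
    """
    ts = np.linspace(0.0, motion.period, n_samples, endpoint=False)
    ts_shift = ts + motion.period / 2.0
    psi_l, phi_l, th_l = motion.angles("left", ts_shift)
    psi_r, phi_r, th_r = motion.angles("right", ts)
    return bool(
        np.max(np.abs(psi_l + psi_r)) <= tol
        and np.max(np.abs(phi_l - phi_r)) <= tol
        and np.max(np.abs(th_l + th_r)) <= tol
    )


def classify_motion(motion: EarMotion, n_samples: int = 256) -> OrbitClassification:
    """Orbit dimensions, hull dimension, and the four condition flags."""
    left = orbit_points(motion, "left", n_samples)
    right = orbit_points(motion, "right", n_samples)
    dims = (affine_dimension(left), affine_dimension(right))
    hull_dim = affine_dimension(np.vstack([left, right]))
    conditions = (
        hull_dim == 3,
        dims[0] >= 2 and dims[1] >= 2,
        not motion.yaw.coincident(),
        not motion.pitch.coincident(),
    )
    return OrbitClassification(
        motion=motion,
        hull_dim=hull_dim,
        orbit_dims=dims,
        conditions=conditions,
        mirror_symmetric=is_mirror_symmetric(motion),
    )


def satisfies_four_conditions(motion: EarMotion) -> bool:
    """Conjunction of the four precise-and-robust detection conditions."""
    return classify_motion(motion).satisfies_all


def phase_shifted_motion(
    amplitude: float = DEFAULT_AMPLITUDE,
    frequency: float = DEFAULT_FREQUENCY,
    delta_phi: float = 180.0,
) -> EarMotion:
    """The phase-difference family of motions.

    Left ear: ``(psi, phi, theta) = (C, C cos(2 pi f t), C sin(2 pi f t))``;
    right ear: ``(-C, C cos(2 pi f t + dPhi), C sin(2 pi f t + dPhi))``.
    ``delta_phi = 180`` reproduces the pattern ``CONST~,COS~,SIN~`` and
    ``delta_phi = 0`` reproduces ``CONST~,COS,SIN``.
    """
    return EarMotion(
        roll=AngleFunctionPair(Pairing.CONST_ANTI, amplitude, frequency),
        pitch=AngleFunctionPair(Pairing.COS, amplitude, frequency, delta_phi),
        yaw=AngleFunctionPair(Pairing.SIN, amplitude, frequency, delta_phi),
    )


def enumerate_motions(
    pitch: Pairing | str | None = None,
    amplitude: float = DEFAULT_AMPLITUDE,
    frequency: float = DEFAULT_FREQUENCY,
) -> list[EarMotion]:
    """All pairing combinations, optionally with the pitch pairing fixed.

    With ``pitch=None`` this is the full 6**3 = 216-motion family; fixing
    ``pitch`` (e.g. to the behaviourally observed ``COS~``) gives the 36
    roll x yaw combinations.
    """
    if pitch is not None and not isinstance(pitch, Pairing):
        pitch = Pairing(pitch)
    pitches = [pitch] if pitch is not None else list(Pairing)
    motions = []
    for r, p, y in itertools.product(list(Pairing), pitches, list(Pairing)):
        motions.append(
            EarMotion(
                roll=AngleFunctionPair(r, amplitude, frequency),
                pitch=AngleFunctionPair(p, amplitude, frequency),
                yaw=AngleFunctionPair(y, amplitude, frequency),
            )
        )
    return motions


def classification_table(motions: list[EarMotion] | None = None) -> pd.DataFrame:
    """Classification of a motion family as a tidy table (one row each)."""
    motions = motions if motions is not None else enumerate_motions()
    rows = []
    for m in motions:
        c = classify_motion(m)
        rows.append(
            {
                "roll": m.roll.pairing.value,
                "pitch": m.pitch.pairing.value,
                "yaw": m.yaw.pairing.value,
                "pattern": m.pattern,
                "hull_dim": c.hull_dim,
                "orbit_dim_left": c.orbit_dims[0],
                "orbit_dim_right": c.orbit_dims[1],
                "dimension_pair": c.dimension_pair,
                "cond_hull_3d": c.conditions[0],
                "cond_orbits_2d": c.conditions[1],
                "cond_yaw_distinct": c.conditions[2],
                "cond_pitch_distinct": c.conditions[3],
                "satisfies_all": c.satisfies_all,
                "mirror_symmetric": c.mirror_symmetric,
            }
        )
    return pd.DataFrame(rows)
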