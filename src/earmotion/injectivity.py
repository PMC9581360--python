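"""Evaluation function U_M and degree of injection I[M].

The forward map M sends a target direction n to the periodic ILD signal
P(t; n).  Direction detection from the ILD alone is possible (and robust)
exactly when M is injective and far from degenerate.  This is scored by

    U_M(n) = sup_{n' != n}  ||n - n'||_2 / ||P(.; n) - P(.; n')||_inf

(worst-case ratio of direction-space distance to signal distance; infinite
where injectivity fails) and summarised over the direction domain X by the
degree of injection

    I[M] = ( integral_X U_M(theta, phi) cos(phi) dtheta dphi )^-1 .

The sup over the continuum is approximated by a max over a uniform
azimuth/elevation grid; signal distances below ``eps_db`` are treated as
degenerate and the ratio is replaced by the finite cap ``u_cap`` so the
integral stays computable.  The quadrature uses angles in radians, so the
numerical value of I is tied to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustics import EarArrayGeometry, SamplingSpec, ild_matrix
from .kinematics import DEFAULT_ANGLE_MAX, EarMotion, direction_vector

__all__ = [
    "DirectionGrid",
    "EvaluationResult",
    "evaluation_function_map",
    "degree_of_injection",
    "evaluate_motion",
]

#: Signal distances below this (dB) count as a violation of injectivity.
DEFAULT_EPS_DB = 1e-9
#: Finite stand-in for the infinite ratio at degenerate pairs.
DEFAULT_U_CAP = 1e6


@dataclass(frozen=True)
class DirectionGrid:
    """A uniform azimuth x elevation grid over the direction domain."""

    theta_values: np.ndarray
    phi_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_values", np.asarray(self.theta_values, float))
        object.__setattr__(self, "phi_values", np.asarray(self.phi_values, float))
        if len(self.theta_values) * len(self.phi_values) < 2:
            raise ValueError("grid must contain at least two directions")

    @classmethod
    def default(
        cls, n: int = 23, angle_max: float = DEFAULT_ANGLE_MAX
    ) -> "DirectionGrid":
        """The standard 23 x 23 grid on |theta|, |phi| <= 60 degrees."""
        vals = np.linspace(-angle_max, angle_max, n)
        return cls(theta_values=vals, phi_values=vals)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.theta_values), len(self.phi_values)

    @property
    def angle_pairs(self) -> np.ndarray:
        """All (theta, phi) pairs, shape ``(n_points, 2)``, degrees."""
        TH, PH = np.meshgrid(self.theta_values, self.phi_values, indexing="ij")
        return np.stack([TH.ravel(), PH.ravel()], axis=1)

    @property
    def unit_vectors(self) -> np.ndarray:
        """Unit direction vectors for every grid point, ``(n_points, 3)``."""
        pairs = self.angle_pairs
        return direction_vector(pairs[:, 0], pairs[:, 1])

    @property
    def cell_solid_angles(self) -> np.ndarray:
        """Quadrature weights cos(phi) dtheta dphi (radians^2) per point."""
        dth = np.deg2rad(np.ptp(self.theta_values)) / max(len(self.theta_values) - 1, 1)
        dph = np.deg2rad(np.ptp(self.phi_values)) / max(len(self.phi_values) - 1, 1)
        pairs = self.angle_pairs
        return np.cos(np.deg2rad(pairs[:, 1])) * dth * dph


@dataclass(frozen=True)
class EvaluationResult:
    """U_M over a grid together with the scalar degree of injection."""

    motion: EarMotion
    grid: DirectionGrid
    U: np.ndarray  #: per grid point, flat, units 1/dB
    I: float  #: degree of injection
    cap_hit: np.ndarray  #: boolean, where the sup was capped

    def to_frame(self) -> pd.DataFrame:
        pairs = self.grid.angle_pairs
        return pd.DataFrame(
            {"theta": pairs[:, 0], "phi": pairs[:, 1], "U": self.U,
             "cap_hit": self.cap_hit}
        )

    def U_map(self) -> np.ndarray:
        """U reshaped to ``(n_theta, n_phi)``."""
        return self.U.reshape(self.grid.shape)


def evaluation_function_map(
    motion: EarMotion,
    grid: DirectionGrid | None = None,
    geometry: EarArrayGeometry | None = None,
    sampling: SamplingSpec | None = None,
    eps_db: float = DEFAULT_EPS_DB,
    u_cap: float = DEFAULT_U_CAP,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """U_M at every grid direction (flat array) and the cap-hit flags.

    For each grid direction the sup in U_M is taken over all *other* grid
    directions, with the discrete sup-norm over the sampled period in the
    denominator and the Euclidean (chord) distance between unit vectors in
    the numerator.
    """
    grid = grid or DirectionGrid.default()
    nd = grid.unit_vectors
    P = ild_matrix(motion, nd, geometry, sampling)
    n = len(nd)
    U = np.empty(n)
    cap_hit = np.zeros(n, dtype=bool)
    # chunked pairwise sup-norms to bound memory at ~chunk*n*n_samples floats
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        sup = np.abs(P[i0:i1, None, :] - P[None, :, :]).max(axis=2)
        dist = np.linalg.norm(nd[i0:i1, None, :] - nd[None, :, :], axis=2)
        degenerate = sup < eps_db
        ratio = np.where(degenerate, u_cap, dist / np.where(degenerate, 1.0, sup))
        ratio[np.arange(i0, i1) - i0, np.arange(i0, i1)] = 0.0  # exclude n' == n
        U[i0:i1] = ratio.max(axis=1)
        cap_hit[i0:i1] = (degenerate & ~np.eye(n, dtype=bool)[i0:i1]).any(axis=1)
    return U, cap_hit


def degree_of_injection(U: np.ndarray, grid: DirectionGrid) -> float:
    """I[M]: reciprocal of the cos(phi)-weighted grid integral of U."""
    total = float(np.sum(np.asarray(U, float) * grid.cell_solid_angles))
    if total <= 0:
        raise RuntimeError("non-positive integral of U; cannot invert")
    return 1.0 / total


def evaluate_motion(
    motion: EarMotion,
    grid: DirectionGrid | None = None,
    geometry: EarArrayGeometry | None = None,
    sampling: SamplingSpec | None = None,
    eps_db: float = DEFAULT_EPS_DB,
    u_cap: float = DEFAULT_U_CAP,
) -> EvaluationResult:
    """Compute U_M and I[M] for one motion on one grid."""
    grid = grid or DirectionGrid.default()
    U, cap_hit = evaluation_function_map(
        motion, grid, geometry, sampling, eps_db=eps_db, u_cap=u_cap
    )
    return EvaluationResult(
        motion=motion, grid=grid, U=U, I=degree_of_injection(U, grid),
        cap_hit=cap_hit,
    )
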