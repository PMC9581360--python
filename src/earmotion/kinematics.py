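"""Periodic rigid ear motions and their SO(3) orientation histories.

An ear motion assigns to each of the three body axes (roll, pitch, yaw) a
*pairing* of left/right periodic angle functions restricted to the 0th and
1st Fourier modes: zero, a constant of opposite sign on the two ears, or a
sine/cosine that is either in phase or in anti-phase across the ears.  The
instantaneous orientation of each ear is the rotation

    L(t) = R_z(theta(t)) @ R_y(-phi(t)) @ R_x(-psi(t))

whose columns are the ear's roll, pitch and yaw axes in head coordinates.

All angles at the public interface are in **degrees**; conversion to
radians happens internally, once.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pairing",
    "Direction",
    "AngleFunctionPair",
    "EarMotion",
    "axis_rotation",
    "orientation_at",
    "orientation_history",
    "evaluate_pair",
    "direction_from_angles",
    "parse_pattern",
]

_DEG = math.pi / 180.0

#: Default half-width of the direction domain, degrees.
DEFAULT_ANGLE_MAX = 60.0
#: Default oscillation amplitude of every non-zero angle function, degrees.
DEFAULT_AMPLITUDE = 15.0
#: Default ear-motion period, seconds (two 33 ms echo windows tile one period).
DEFAULT_PERIOD = 0.066
#: Default ear-motion frequency, Hz.
DEFAULT_FREQUENCY = 1.0 / DEFAULT_PERIOD


class Pairing(enum.Enum):
    """Left/right angle-function pairing types.

    The ``*_ANTI`` members are the anti-phase pairings in which the right
    ear's function is the negative of the left ear's (the behaviourally
    observed mode for the pitch axis of horseshoe bats).
    """

    ZERO = "0"
    CONST_ANTI = "CONST~"
    SIN = "SIN"
    SIN_ANTI = "SIN~"
    COS = "COS"
    COS_ANTI = "COS~"

    @property
    def is_anti_phase(self) -> bool:
        return self in (Pairing.CONST_ANTI, Pairing.SIN_ANTI, Pairing.COS_ANTI)

    @property
    def is_oscillating(self) -> bool:
        return self in (Pairing.SIN, Pairing.SIN_ANTI, Pairing.COS, Pairing.COS_ANTI)


def parse_pairing(token: str) -> Pairing:
    """Parse a single pairing token such as ``"COS~"`` (``~`` = anti-phase)."""
    try:
        return Pairing(token.strip())
    except ValueError:
        valid = ", ".join(p.value for p in Pairing)
        raise ValueError(f"unknown pairing token {token!r}; expected one of: {valid}")


@dataclass(frozen=True)
class Direction:
    """A target direction given by azimuth/elevation, with its unit vector.

    The unit vector convention is
    ``n = (cos(theta) cos(phi), sin(theta) cos(phi), sin(phi))``
    with the x axis pointing straight ahead, y to the animal's left and z up.
    """

    theta: float  #: azimuth, degrees
    phi: float  #: elevation, degrees
    theta_max: float = DEFAULT_ANGLE_MAX
    phi_max: float = DEFAULT_ANGLE_MAX

    def __post_init__(self) -> None:
        if not (math.isfinite(self.theta) and math.isfinite(self.phi)):
            raise ValueError("direction angles must be finite")
        if abs(self.phi) >= 90.0:
            raise ValueError("elevation must lie in (-90, 90) degrees")
        if abs(self.theta) > self.theta_max or abs(self.phi) > self.phi_max:
            raise ValueError(
                f"direction ({self.theta}, {self.phi}) outside the "
                f"±{self.theta_max}/±{self.phi_max} degree domain"
            )

    @property
    def n(self) -> np.ndarray:
        """Unit direction vector in head coordinates."""
        return direction_vector(self.theta, self.phi)


def direction_vector(theta_deg, phi_deg) -> np.ndarray:
    """Unit vector(s) for azimuth/elevation in degrees (vectorised).

    For array inputs of shape ``s`` the result has shape ``s + (3,)``.
    """
    t = np.asarray(theta_deg, dtype=float) * _DEG
    p = np.asarray(phi_deg, dtype=float) * _DEG
    return np.stack(
        [np.cos(t) * np.cos(p), np.sin(t) * np.cos(p), np.sin(p)], axis=-1
    )


def direction_from_angles(
    theta: float, phi: float, theta_max: float = DEFAULT_ANGLE_MAX,
    phi_max: float = DEFAULT_ANGLE_MAX,
) -> Direction:
    """Construct a validated :class:`Direction` from angles in degrees."""
    return Direction(theta=theta, phi=phi, theta_max=theta_max, phi_max=phi_max)


@dataclass(frozen=True)
class AngleFunctionPair:
    """A left/right pair of periodic angle functions for one rotation axis.

    ``phase_offset`` (degrees) is added to the argument of the *right* ear's
    oscillating function only; it is used by the phase-difference sweep and
    is zero for all plain Table-type pairings.
    """

    pairing: Pairing
    amplitude: float = DEFAULT_AMPLITUDE  #: C, degrees
    frequency: float = DEFAULT_FREQUENCY  #: f_e, Hz
    phase_offset: float = 0.0  #: ΔΦ, degrees, right ear only

    def __post_init__(self) -> None:
        if not isinstance(self.pairing, Pairing):
            object.__setattr__(self, "pairing", parse_pairing(str(self.pairing)))
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def period(self) -> float:
        """T = 1/f_e, seconds."""
        return 1.0 / self.frequency

    def _base(self, t, extra_phase_deg: float):
        """The oscillatory factor for one ear, degrees."""
        t = np.asarray(t, dtype=float)
        arg = 2.0 * math.pi * self.frequency * t + extra_phase_deg * _DEG
        C = self.amplitude
        p = self.pairing
        if p is Pairing.ZERO:
            return np.zeros_like(t)
        if p is Pairing.CONST_ANTI:
            return np.full_like(t, C)
        if p in (Pairing.SIN, Pairing.SIN_ANTI):
            return C * np.sin(arg)
        return C * np.cos(arg)

    def left(self, t):
        """Left-ear angle at time(s) ``t`` (seconds), degrees."""
        return self._base(t, 0.0)

    def right(self, t):
        """Right-ear angle at time(s) ``t`` (seconds), degrees."""
        sign = -1.0 if self.pairing.is_anti_phase else 1.0
        return sign * self._base(t, self.phase_offset)

    def coincident(self, tol: float = 1e-9, n_samples: int = 64) -> bool:
        """Whether the left and right functions are identical as functions.

        Decided analytically from the pairing name when no phase offset is
        present (exact for the six pairing types); otherwise by sampling.
        """
        if self.phase_offset == 0.0 or not self.pairing.is_oscillating:
            if self.pairing is Pairing.ZERO:
                return True
            if self.pairing.is_anti_phase:
                # left == -right; coincide only if identically zero
                return self.amplitude == 0.0
            return True
        ts = np.linspace(0.0, self.period, n_samples, endpoint=False)
        return bool(np.max(np.abs(self.left(ts) - self.right(ts))) <= tol)


def evaluate_pair(pair: AngleFunctionPair, t):
    """Evaluate ``(left_angle, right_angle)`` in degrees at time(s) ``t``."""
    if not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError("time must be finite")
    return pair.left(t), pair.right(t)


@dataclass(frozen=True)
class EarMotion:
    """Periodic motion of both ears: one angle-function pair per axis."""

    roll: AngleFunctionPair
    pitch: AngleFunctionPair
    yaw: AngleFunctionPair

    def __post_init__(self) -> None:
        fs = {self.roll.frequency, self.pitch.frequency, self.yaw.frequency}
        if len(fs) != 1:
            raise ValueError("all three angle-function pairs must share f_e")

    @property
    def frequency(self) -> float:
        return self.roll.frequency

    @property
    def period(self) -> float:
        return self.roll.period

    @property
    def pattern(self) -> str:
        """Canonical 3-token name, e.g. ``"SIN,COS~,CONST~"``."""
        return ",".join(p.pairing.value for p in (self.roll, self.pitch, self.yaw))

    @classmethod
    def from_pattern(
        cls,
        pattern: str,
        amplitude: float = DEFAULT_AMPLITUDE,
        frequency: float = DEFAULT_FREQUENCY,
    ) -> "EarMotion":
        """Build a motion from a 3-token pattern like ``"SIN,COS~,CONST~"``.

        The tokens name the roll, pitch and yaw pairings in that order; a
        trailing ``~`` marks an anti-phase pairing.
        """
        tokens = [s.strip() for s in pattern.split(",")]
        if len(tokens) != 3:
            raise ValueError(f"pattern {pattern!r} must have 3 comma-separated tokens")
        pairs = [
            AngleFunctionPair(parse_pairing(tok), amplitude, frequency)
            for tok in tokens
        ]
        return cls(roll=pairs[0], pitch=pairs[1], yaw=pairs[2])

    def angles(self, side: str, t):
        """(psi, phi, theta) angle histories for one ear, degrees."""
        fns = {"left": lambda p: p.left(t), "right": lambda p: p.right(t)}
        try:
            f = fns[side]
        except KeyError:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return f(self.roll), f(self.pitch), f(self.yaw)


def parse_pattern(pattern: str, **kwargs) -> EarMotion:
    """Alias for :meth:`EarMotion.from_pattern`."""
    return EarMotion.from_pattern(pattern, **kwargs)


def axis_rotation(axis: str, angle_deg: float) -> np.ndarray:
    """Right-handed active rotation matrix about a fixed body axis.

    Parameters
    ----------
    axis:
        One of ``"x"``, ``"y"``, ``"z"``.
    angle_deg:
        Rotation angle in degrees.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(a * _DEG), np.sin(a * _DEG)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"axis must be one of x, y, z; got {axis!r}")


def _rotation_history(psi_deg, phi_deg, theta_deg) -> np.ndarray:
    """Stacked L = R_z(theta) R_y(-phi) R_x(-psi) for arrays of angles (deg).

    Vectorised closed form of the triple product; returns shape ``(n, 3, 3)``.
    """
    psi = np.asarray(psi_deg, dtype=float) * _DEG
    phi = np.asarray(phi_deg, dtype=float) * _DEG
    th = np.asarray(theta_deg, dtype=float) * _DEG
    cps, sps = np.cos(-psi), np.sin(-psi)
    cph, sph = np.cos(-phi), np.sin(-phi)
    ct, st = np.cos(th), np.sin(th)
    L = np.empty(np.broadcast(psi, phi, th).shape + (3, 3))
    L[..., 0, 0] = ct * cph
    L[..., 0, 1] = ct * sph * sps - st * cps
    L[..., 0, 2] = ct * sph * cps + st * sps
    L[..., 1, 0] = st * cph
    L[..., 1, 1] = st * sph * sps + ct * cps
    L[..., 1, 2] = st * sph * cps - ct * sps
    L[..., 2, 0] = -sph
    L[..., 2, 1] = cph * sps
    L[..., 2, 2] = cph * cps
    return L


def orientation_at(motion: EarMotion, side: str, t: float) -> np.ndarray:
    """Ear orientation L(t) in SO(3); columns are the roll/pitch/yaw axes."""
    if not np.all(np.isfinite(np.asarray(t, dtype=float))):
        raise ValueError("time must be finite")
    psi, phi, th = motion.angles(side, t)
    return _rotation_history(psi, phi, th)


def orientation_history(motion: EarMotion, side: str, times) -> np.ndarray:
    """Orientation matrices at an array of times; shape ``(len(times), 3, 3)``."""
    return orientation_at(motion, side, np.asarray(times, dtype=float))
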