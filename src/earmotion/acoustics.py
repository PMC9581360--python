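"""Forward acoustic model: ear directivity, envelopes, and the ILD signal.

Each virtual ear is a rectangle of four omnidirectional microphones whose
coherently summed plane-wave response gives the directional gain

    S_env = 4 A cos(pi * delta_y * ny / lambda) * cos(pi * delta_z * nz / lambda)

where ``(nx, ny, nz)`` is the target direction expressed in the rotating ear
frame.  The interaural level difference (the model's sole directional cue) is

    P(t; n) = 20 log10( S_env_left / S_env_right )   [dB]

sampled at 1 ms over one motion period.  Under the far-field plane-wave
assumption the ratio cancels the source amplitude, the target distance and
the rigid placement of the ears, so ``P`` depends only on the two
orientation histories and the direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import Direction, EarMotion, orientation_history

__all__ = [
    "EarArrayGeometry",
    "SamplingSpec",
    "ILDSignal",
    "envelope_at",
    "brute_force_envelope",
    "ild_signal",
    "ild_matrix",
    "quantize_ild",
]

#: Echo wavelength, mm (70 kHz carrier in air).
DEFAULT_WAVELENGTH = 5.0
#: Microphone spacing as a fraction of the wavelength ("slightly smaller
#: than half"); calibrated against the published injectivity values.
DEFAULT_SPACING_FRACTION = 0.49


@dataclass(frozen=True)
class EarArrayGeometry:
    """Four-microphone rectangular ear array and source amplitude.

    ``ear_spacing`` (the left–right distance d) is retained for completeness
    but cancels out of the ILD under the plane-wave assumption.
    """

    delta_y: float = DEFAULT_SPACING_FRACTION * DEFAULT_WAVELENGTH  #: mm
    delta_z: float = DEFAULT_SPACING_FRACTION * DEFAULT_WAVELENGTH  #: mm
    wavelength: float = DEFAULT_WAVELENGTH  #: mm
    amplitude: float = 1.0  #: received amplitude at the origin, arbitrary units
    ear_spacing: float = 15.0  #: mm, unused by the far-field model

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.amplitude <= 0:
            raise ValueError("wavelength and amplitude must be positive")
        half = self.wavelength / 2.0
        if not (0 <= self.delta_y < half and 0 <= self.delta_z < half):
            raise ValueError(
                "microphone spacings must satisfy 0 <= delta < wavelength/2 "
                "(this guarantees a strictly positive envelope)"
            )


@dataclass(frozen=True)
class SamplingSpec:
    """Uniform time discretisation of one motion period."""

    dt: float = 1.0  #: sample interval, ms
    period: float = 66.0  #: motion period T, ms

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.period <= 0:
            raise ValueError("dt and period must be positive")
        n = self.period / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("period must be an integer multiple of dt")

    @property
    def n_samples(self) -> int:
        return int(round(self.period / self.dt))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample instants covering [0, T), ms."""
        return np.arange(self.n_samples) * self.dt

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms * 1e-3


@dataclass(frozen=True)
class ILDSignal:
    """A sampled periodic ILD time series."""

    times_ms: np.ndarray
    values_db: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, float))
        object.__setattr__(self, "values_db", np.asarray(self.values_db, float))
        if self.times_ms.shape != self.values_db.shape:
            raise ValueError("times and values must have the same shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times_ms, "ild_db": self.values_db})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_rotation(L: np.ndarray) -> None:
    L = np.asarray(L, float)
    if L.shape[-2:] != (3, 3) or not np.allclose(
        np.swapaxes(L, -1, -2) @ L, np.eye(3), atol=1e-9
    ):
        raise ValueError("L must be a (stack of) orthogonal 3x3 matrices")


def envelope_at(geometry: EarArrayGeometry, L: np.ndarray, n) -> float:
    """Received envelope for one ear orientation and target direction.

    ``n`` may be a :class:`Direction` or a unit 3-vector.  Uses the closed
    form ``4 A cos(pi dy ny~ / lam) cos(pi dz nz~ / lam)`` with the direction
    rotated into the ear frame, ``n~ = L.T n``.
    """
    _check_rotation(L)
    nv = n.n if isinstance(n, Direction) else np.asarray(n, float)
    nt = np.asarray(L, float).T @ nv
    lam = geometry.wavelength
    return (
        4.0
        * geometry.amplitude
        * math.cos(math.pi * geometry.delta_y * nt[1] / lam)
        * math.cos(math.pi * geometry.delta_z * nt[2] / lam)
    )


def brute_force_envelope(geometry: EarArrayGeometry, L: np.ndarray, n) -> float:
    """Independent phasor-sum oracle for :func:`envelope_at`.

    Places the four omnidirectional receivers at the ear-frame rectangle
    vertices ``(0, ±delta_y/2, ±delta_z/2)``, rotates them by ``L``, and sums
    the plane-wave phasors ``exp(2i pi (r_k · n) / lambda)`` explicitly.
    """
    _check_rotation(L)
    nv = n.n if isinstance(n, Direction) else np.asarray(n, float)
    dy, dz = geometry.delta_y / 2.0, geometry.delta_z / 2.0
    offsets = np.array(
        [[0, sy * dy, sz * dz] for sy in (+1, -1) for sz in (+1, -1)]
    )
    positions = offsets @ np.asarray(L, float).T  # r_k = L u_k, row-wise
    phases = 2.0 * math.pi * (positions @ nv) / geometry.wavelength
    return geometry.amplitude * abs(np.exp(1j * phases).sum())


def _envelopes_over_period(
    motion: EarMotion,
    directions: np.ndarray,
    geometry: EarArrayGeometry,
    sampling: SamplingSpec,
    side: str,
) -> np.ndarray:
    """Envelope samples, shape ``(n_directions, n_samples)``."""
    L = orientation_history(motion, side, sampling.times_s)
    # n~[d, t, :] = L(t).T n_d
    nt = np.einsum("tji,dj->dti", L, directions)
    lam = geometry.wavelength
    env = (
        4.0
        * geometry.amplitude
        * np.cos(np.pi * geometry.delta_y * nt[..., 1] / lam)
        * np.cos(np.pi * geometry.delta_z * nt[..., 2] / lam)
    )
    if np.any(env <= 0):
        raise ValueError(
            "non-positive envelope encountered; geometry is degenerate "
            "(requires delta_y, delta_z < wavelength/2)"
        )
    return env


def ild_matrix(
    motion: EarMotion,
    directions: np.ndarray,
    geometry: EarArrayGeometry | None = None,
    sampling: SamplingSpec | None = None,
) -> np.ndarray:
    """ILD signals for many directions at once; shape ``(n_dirs, n_samples)``.

    ``directions`` is an ``(n, 3)`` array of unit vectors.  This is the
    vectorised core used by the injectivity and learning modules.
    """
    geometry = geometry or EarArrayGeometry()
    sampling = sampling or SamplingSpec()
    directions = np.atleast_2d(np.asarray(directions, float))
    env_l = _envelopes_over_period(motion, directions, geometry, sampling, "left")
    env_r = _envelopes_over_period(motion, directions, geometry, sampling, "right")
    return 20.0 * np.log10(env_l / env_r)


def ild_signal(
    motion: EarMotion,
    direction,
    geometry: EarArrayGeometry | None = None,
    sampling: SamplingSpec | None = None,
) -> ILDSignal:
    """The ILD time series P(t; n) over one motion period."""
    sampling = sampling or SamplingSpec()
    nv = direction.n if isinstance(direction, Direction) else np.asarray(direction)
    values = ild_matrix(motion, nv[None, :], geometry, sampling)[0]
    return ILDSignal(times_ms=sampling.times_ms, values_db=values)


def quantize_ild(signal, step: float):
    """Round ILD values to the nearest multiple of ``step`` dB.

    ``step = 0`` returns the input unchanged.  Exact midpoints round half-up.
    Accepts an :class:`ILDSignal` or a bare array and returns the same kind.
    """
    if step < 0:
        raise ValueError("quantization step must be non-negative")
    if step == 0:
        return signal
    if isinstance(signal, ILDSignal):
        return ILDSignal(signal.times_ms, quantize_ild(signal.values_db, step))
    x = np.asarray(signal, float)
    return np.floor(x / step + 0.5) * step
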