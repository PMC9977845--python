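"""Hydrogen-bond occupancy over geometric time series.

The occupancy of a hydrogen bond over a trajectory is the fraction of
frames in which a geometric criterion is met.  The default criterion is
the common MD convention: donor-acceptor distance <= 0.35 nm and
donor-H-acceptor angle >= 150 degrees (i.e. within 30 degrees of
linearity).  Input is a plain per-frame table of distance (nm) and an
optional angle (degrees), deliberately decoupled from any trajectory
format: frames lacking an angle are judged on distance alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .errors import InsufficientDataError, ValidationError

DEFAULT_DIST_CUTOFF_NM = 0.35
DEFAULT_ANGLE_CUTOFF_DEG = 30.0  # accepted deviation from 180 degrees

__all__ = [
    "GeometricTrace",
    "hbond_occupancy",
    "hbond_counts",
    "DEFAULT_DIST_CUTOFF_NM",
    "DEFAULT_ANGLE_CUTOFF_DEG",
]


@dataclass(frozen=True)
class GeometricTrace:
    """Ordered per-frame hydrogen-bond geometry.

    ``frames`` holds ``(distance_nm, angle_deg)`` records; ``angle_deg``
    is ``None`` for frames without angle information.
    """

    frames: tuple[tuple[float, float | None], ...]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValidationError("a trace needs at least one frame")
        for i, (d, a) in enumerate(self.frames):
            if d < 0:
                raise ValidationError(f"frame {i}: negative distance {d}")
            if a is not None and not 0 <= a <= 180:
                raise ValidationError(f"frame {i}: angle {a} outside [0, 180]")

    @classmethod
    def from_sequences(
        cls,
        distances: Sequence[float],
        angles: Sequence[float] | None = None,
    ) -> "GeometricTrace":
        if angles is None:
            return cls(tuple((float(d), None) for d in distances))
        if len(angles) != len(distances):
            raise ValidationError("distances and angles differ in length")
        return cls(tuple((float(d), float(a)) for d, a in zip(distances, angles)))

    @property
    def frame_count(self) -> int:
        return len(self.frames)

    def concat(self, other: "GeometricTrace") -> "GeometricTrace":
        return GeometricTrace(self.frames + other.frames)


def hbond_counts(
    trace: GeometricTrace,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF_NM,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF_DEG,
) -> tuple[int, int]:
    """``(bonded_frames, total_frames)`` under the geometric criterion.

    A frame is bonded when distance <= ``dist_cutoff`` and, if an angle
    is recorded, angle >= 180 - ``angle_cutoff``.
    """
    if not (dist_cutoff > 0 and angle_cutoff > 0):
        raise ValidationError("cutoffs must be positive")
    bonded = sum(
        1
        for d, a in trace.frames
        if d <= dist_cutoff and (a is None or a >= 180.0 - angle_cutoff)
    )
    return bonded, trace.frame_count


def hbond_occupancy(
    trace: GeometricTrace,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF_NM,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF_DEG,
) -> float:
    """Fraction of frames satisfying the hydrogen-bond criterion.

    Computed as the exact rational bonded/total count; monotone
    non-decreasing in both cutoffs.
    """
    bonded, total = hbond_counts(trace, dist_cutoff, angle_cutoff)
    if total == 0:
        raise InsufficientDataError("empty trace")
    return float(Fraction(bonded, total))
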