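"""Equilibrium binding model and Scatchard analysis.

The model is the classical n-identical-independent-sites equilibrium for a
ligand binding a DNA duplex host.  With total ligand concentration ``c``,
total duplex concentration ``M`` and free-ligand concentration ``L`` (all
in uM), the average occupancy of the host is

    v = (c - L) / M

and for n identical, independent sites with dissociation constant Kd the
Scatchard relation holds:

    v / L = (n - v) / Kd

so a Scatchard plot of v/L against v is a line of slope -1/Kd with
x-intercept n.  Experimental Scatchard plots bend near saturation, which
is handled by a two-segment piecewise regression: a sloped line in the
binding regime plus a plateau (v ~ n) in the saturation regime.

All concentrations are uM throughout the package (the titrations use
0.01 mM = 10 uM ligand and Kd values fall in the 0.03-0.6 uM range).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    NoBindingSignalError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Scatchard points with free-ligand concentration below this (uM) are
#: dropped rather than clamped: they would contribute fabricated leverage.
L_FLOOR_UM = 1e-9

#: Free-ligand molar fraction below which a titration point is considered
#: saturated (the free species is no longer quantifiable from the spectra)
#: and is excluded from the Scatchard fit.
DEFAULT_MIN_FREE_FRACTION = 0.05

#: Points with free fraction >= this are "well-determined"; fewer than
#: MIN_RELIABLE_POINTS of them marks the fitted Kd as an estimation only.
RELIABLE_FREE_FRACTION = 0.10
MIN_RELIABLE_POINTS = 3

__all__ = [
    "TitrationPoint",
    "BindingResult",
    "solve_free_ligand",
    "occupancy",
    "scatchard_points",
    "fit_kd_piecewise",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: totals plus derived free ligand and occupancy.

    Invariants ``0 <= L <= c`` and ``v == (c - L)/M`` are enforced at
    construction; ``v * M + L == c`` therefore holds to machine precision.
    """

    c: float  # total ligand, uM
    M: float  # total DNA duplex, uM
    L: float  # free ligand, uM
    v: float = field(init=False)  # average occupancy (c - L)/M

    def __post_init__(self) -> None:
        if self.c < 0 or self.M < 0:
            raise ValidationError("concentrations must be non-negative")
        if not (-1e-12 <= self.L <= self.c * (1 + 1e-12) + 1e-12):
            raise ValidationError(
                f"free ligand L={self.L} outside [0, c={self.c}]"
            )
        object.__setattr__(self, "L", min(max(self.L, 0.0), self.c))
        v = (self.c - self.L) / self.M if self.M > 0 else math.nan
        object.__setattr__(self, "v", v)

    @property
    def free_fraction(self) -> float:
        """Molar fraction of ligand that is free, L/c."""
        return self.L / self.c if self.c > 0 else math.nan


@dataclass
class BindingResult:
    """Outcome of a Scatchard piecewise regression.

    ``estimate_flag`` marks fits resting on too few well-determined points
    (fewer than 3 sub-saturation points, or a binding-regime segment of
    fewer than 3 points); such Kd values are estimations, not
    determinations.
    """

    Kd: float  # uM
    n: float  # identical independent sites per duplex
    scatchard: list[tuple[float, float]]  # (v, v/L) pairs used in the fit
    breakpoint: float | None  # v separating the segments, None if single-line
    fit_quality: dict[str, float]  # residual sum of squares per segment
    estimate_flag: bool
    n_plateau: float | None = None  # plateau-mean cross-check of n
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.Kd > 0 and self.n > 0):
            raise ValidationError("fitted Kd and n must be positive")


def solve_free_ligand(c: float, M: float, Kd: float, n: float = 1.0) -> float:
    """Free-ligand concentration at equilibrium (uM).

    Solves the mass balance ``L + n*M*L/(Kd + L) = c`` for the unique root
    in [0, c]; the bound term is single-site-class Langmuir binding to
    ``n`` identical independent sites on each of ``M`` duplexes.  The
    quadratic ``L**2 + (Kd + n*M - c)*L - c*Kd = 0`` has exactly one
    non-negative root, taken in closed form.
    """
    if c < 0 or M < 0:
        raise ValidationError("c and M must be non-negative")
    if not (Kd > 0 and n > 0):
        raise ValidationError("Kd and n must be positive")
    if c == 0:
        return 0.0
    b = Kd + n * M - c
    # numerically stable positive root of L^2 + b L - c Kd = 0
    disc = math.sqrt(b * b + 4.0 * c * Kd)
    L = (disc - b) / 2.0 if b <= 0 else (2.0 * c * Kd) / (disc + b)
    L = min(max(L, 0.0), c)
    residual = L + n * M * L / (Kd + L) - c
    if abs(residual) > 1e-10 * max(c, 1.0):
        raise ArithmeticError(
            f"mass-balance residual {residual:g} exceeds tolerance"
        )
    return L


def occupancy(c: float, L: float, M: float) -> float:
    """Average occupancy of the DNA host by ligand, v = (c - L)/M."""
    if M <= 0:
        raise ValidationError("occupancy undefined for M <= 0")
    if L < 0 or L > c:
        raise ValidationError(f"free ligand L={L} outside [0, c={c}]")
    return (c - L) / M


def scatchard_points(
    points: list[TitrationPoint],
    min_free_fraction: float = 0.0,
) -> list[tuple[float, float]]:
    """Scatchard coordinates (v, v/L) for a titration, input order kept.

    Points with ``L`` below the working floor are excluded with a warning
    (their ordinate is unbounded).  ``min_free_fraction`` optionally
    excludes saturated points whose free-ligand molar fraction L/c falls
    below the quantifiable level; the end-to-end pipeline uses this to
    keep noise-dominated near-saturation points out of the regression.
    """
    out: list[tuple[float, float]] = []
    for i, p in enumerate(points):
        if p.M <= 0:
            logger.warning("Scatchard point %d dropped: no DNA (M=0)", i)
            continue
        if p.L < L_FLOOR_UM:
            logger.warning(
                "Scatchard point %d dropped: free ligand %.3g uM below floor",
                i, p.L,
            )
            continue
        if p.free_fraction < min_free_fraction:
            logger.info(
                "Scatchard point %d dropped as saturated: free fraction "
                "%.3g < %.3g", i, p.free_fraction, min_free_fraction,
            )
            continue
        out.append((p.v, p.v / p.L))
    return out


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line y = a + s x; returns (slope, intercept, rss)."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    s, a = float(coef[0]), float(coef[1])
    rss = float(np.sum((y - (a + s * x)) ** 2))
    return s, a, rss


def fit_kd_piecewise(
    scatchard: list[tuple[float, float]],
    n_reliable_points: int | None = None,
) -> BindingResult:
    """Estimate Kd and n from Scatchard coordinates by piecewise regression.

    Points are ordered by v and split by an exhaustive breakpoint search
    over inter-point midpoints into a binding-regime line (v below the
    breakpoint; slope -1/Kd, x-intercept n, residuals in v/L) and a
    saturation plateau (v ~ n; residuals in v).  Each segment needs at
    least 2 points; if no valid split improves on a single line over all
    points, the single-line fit is returned with ``breakpoint=None``.

    ``n_reliable_points``, when given by the caller (the titration
    pipeline), is the number of well-determined sub-saturation points; a
    value below 3 raises ``estimate_flag`` regardless of the segmentation,
    mirroring Kd values "established upon only two experimental points".
    """
    if len(scatchard) < 2:
        raise InsufficientDataError(
            f"piecewise Scatchard fit needs >= 2 points, got {len(scatchard)}"
        )
    pts = sorted(scatchard)
    v = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)

    s_all, a_all, rss_all = _line_fit(v, y)
    best: dict = {
        "rss": rss_all, "breakpoint": None, "slope": s_all,
        "intercept": a_all, "seg1_size": len(pts),
        "fit_quality": {"segment1_rss": rss_all},
        "plateau": None,
    }
    # breakpoint grid: midpoints between consecutive ordered v values,
    # keeping >= 2 points per segment
    for k in range(2, len(pts) - 1):
        if v[k - 1] == v[k]:
            continue
        bp = 0.5 * (v[k - 1] + v[k])
        s1, a1, rss1 = _line_fit(v[:k], y[:k])
        if s1 >= 0:
            continue  # not a binding-regime line
        plateau = float(np.mean(v[k:]))
        rss2 = float(np.sum((v[k:] - plateau) ** 2))
        total = rss1 + rss2
        if total < best["rss"] * (1 - 1e-12):
            best = {
                "rss": total, "breakpoint": bp, "slope": s1,
                "intercept": a1, "seg1_size": k,
                "fit_quality": {"segment1_rss": rss1, "segment2_rss": rss2},
                "plateau": plateau,
            }

    slope = best["slope"]
    if slope >= 0:
        raise NoBindingSignalError(
            f"non-negative Scatchard slope ({slope:.3g}): no binding signal"
        )
    Kd = -1.0 / slope
    n = -best["intercept"] / slope  # x-intercept of the segment-1 line
    if n <= 0:
        raise NoBindingSignalError(
            f"non-positive fitted site count n={n:.3g}"
        )
    n_plateau = best["plateau"]
    if n_plateau is not None and abs(n_plateau - n) > 0.20 * n:
        logger.warning(
            "plateau-mean n=%.3g disagrees with x-intercept n=%.3g by >20%%",
            n_plateau, n,
        )
    flag = best["seg1_size"] < 3
    if n_reliable_points is not None and n_reliable_points < MIN_RELIABLE_POINTS:
        flag = True
    return BindingResult(
        Kd=Kd,
        n=n,
        scatchard=pts,
        breakpoint=best["breakpoint"],
        fit_quality=best["fit_quality"],
        estimate_flag=flag,
        n_plateau=n_plateau,
    )
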