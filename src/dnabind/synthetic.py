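"""Synthetic inputs with known ground truth.

The raw UV-VIS spectra and MD trajectories behind the study design this
package re-implements are not published, so every pipeline input is
generated here at desk scale:

- two-species Beer-Lambert titration spectra with a known dissociation
  constant, at the experimental design points (constant 10 uM ligand,
  DNA:ligand ratios 0.25-7 plus a ligand-only reference);
- stochastic hydrogen-bond geometry traces (i.i.d. Bernoulli or
  two-state Markov) with a prescribed stationary bonded probability.

The default pure spectra — a free-ligand Gaussian band at 420 nm and a
bound band red-shifted to 440 nm with 20% hypochromism on a 350-550 nm
grid — are generic intercalator-like signatures in a DNA-transparent
window, not measurements of any real chromophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import solve_free_ligand
from .chemometrics import TitrationSeries
from .errors import ValidationError
from .occupancy import GeometricTrace

#: The experimental titration design: DNA:ligand molar ratios, preceded
#: by a ligand-only reference point that anchors the free-state score.
DESIGN_RATIOS = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.0)
DEFAULT_RATIOS = (0.0,) + DESIGN_RATIOS

DEFAULT_LIGAND_TOTAL_UM = 10.0  # 0.01 mM

BONDED_DISTANCE_NM = 0.28
UNBONDED_DISTANCE_NM = 0.50

__all__ = [
    "PureSpectrum",
    "SimulationConfig",
    "evaluate_spectrum",
    "default_free_spectrum",
    "default_bound_spectrum",
    "simulate_titration",
    "simulate_hbond_trace",
    "DESIGN_RATIOS",
    "DEFAULT_RATIOS",
    "DEFAULT_LIGAND_TOTAL_UM",
]


@dataclass(frozen=True)
class PureSpectrum:
    """A pure-component absorption spectrum as a sum of Gaussian bands.

    ``bands`` holds ``(center_nm, width_nm, amplitude)`` triples; the
    evaluated spectrum is non-negative everywhere by construction.
    """

    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, amp in self.bands:
            if width <= 0:
                raise ValidationError(f"band width must be positive, got {width}")
            if amp < 0:
                raise ValidationError(f"band amplitude must be >= 0, got {amp}")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        return evaluate_spectrum(self, wavelengths)


def evaluate_spectrum(pure: PureSpectrum, wavelengths: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands ``amp * exp(-(wl-center)^2 / (2 width^2))``."""
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for center, width, amp in pure.bands:
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def default_free_spectrum() -> PureSpectrum:
    return PureSpectrum(bands=((420.0, 20.0, 1.0),))


def default_bound_spectrum() -> PureSpectrum:
    """Red-shifted by 20 nm with 20% hypochromism relative to the free band."""
    return PureSpectrum(bands=((440.0, 20.0, 0.8),))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated titration."""

    Kd: float  # uM
    n: float = 1.0
    ligand_total: float = DEFAULT_LIGAND_TOTAL_UM  # uM
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    noise_sd: float = 0.0  # absorbance units
    seed: int = 0
    wavelength_lo: float = 350.0
    wavelength_hi: float = 550.0
    wavelength_step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Kd > 0 and self.n > 0 and self.ligand_total > 0):
            raise ValidationError("Kd, n and ligand_total must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_lo,
            self.wavelength_hi + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )


def simulate_titration(
    config: SimulationConfig,
    free_spec: PureSpectrum | None = None,
    bound_spec: PureSpectrum | None = None,
) -> tuple[TitrationSeries, np.ndarray]:
    """Forward-model a two-species titration with known ground truth.

    At each DNA:ligand ratio ``r`` the free-ligand concentration solves
    the n-site mass balance at ``M = r * c``; the column is
    ``x_free * S_free + x_bound * S_bound`` plus seeded i.i.d. Gaussian
    noise.  Returns the series and the ground-truth bound fractions.
    """
    free_spec = free_spec or default_free_spectrum()
    bound_spec = bound_spec or default_bound_spectrum()
    wl = config.wavelengths
    s_free = evaluate_spectrum(free_spec, wl)
    s_bound = evaluate_spectrum(bound_spec, wl)
    cross = float(np.dot(s_free, s_bound))
    norms = float(np.linalg.norm(s_free) * np.linalg.norm(s_bound))
    if norms == 0 or 1.0 - abs(cross) / norms < 1e-10:
        raise ValidationError(
            "free and bound pure spectra are proportional: the titration "
            "carries no shape information"
        )

    c = config.ligand_total
    x_bound = np.empty(len(config.ratios))
    columns = np.empty((wl.size, len(config.ratios)))
    for j, ratio in enumerate(config.ratios):
        L = solve_free_ligand(c, ratio * c, config.Kd, config.n)
        x_free = L / c
        x_bound[j] = 1.0 - x_free
        columns[:, j] = x_free * s_free + x_bound[j] * s_bound
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        columns = columns + rng.normal(0.0, config.noise_sd, size=columns.shape)
    series = TitrationSeries(
        wavelengths=wl,
        absorbance=columns,
        ligand_total=c,
        dna_ratios=np.asarray(config.ratios, dtype=float),
        absorbance_floor=min(-0.01, float(columns.min()) - 1e-12),
    )
    return series, x_bound


def simulate_hbond_trace(
    p: float,
    frame_count: int,
    model: str = "iid",
    persistence: float = 0.9,
    seed: int = 0,
) -> GeometricTrace:
    """Stochastic two-state hydrogen-bond trace with stationary bonded
    probability ``p``.

    Bonded frames sit at 0.28 nm, unbonded at 0.50 nm (no angles).
    ``model="iid"`` draws frames independently; ``model="markov"`` uses a
    two-state chain with extra persistence ``rho`` (stay probabilities
    ``p + rho*(1-p)`` bonded, ``1 - p*(1-rho)`` unbonded), which keeps
    the stationary distribution at ``p`` while correlating frames.
    """
    if not 0 <= p <= 1:
        raise ValidationError(f"bonded probability p={p} outside [0, 1]")
    if frame_count < 1:
        raise ValidationError("frame_count must be >= 1")
    rng = np.random.default_rng(seed)
    if model == "iid":
        bonded = rng.random(frame_count) < p
    elif model == "markov":
        if not 0 <= persistence < 1:
            raise ValidationError("persistence must be in [0, 1)")
        a = p + persistence * (1.0 - p)  # P(bonded -> bonded)
        b = p * (1.0 - persistence)  # P(unbonded -> bonded)
        u = rng.random(frame_count)
        bonded = np.empty(frame_count, dtype=bool)
        bonded[0] = u[0] < p  # start from the stationary distribution
        for t in range(1, frame_count):
            bonded[t] = u[t] < (a if bonded[t - 1] else b)
    else:
        raise ValidationError(f"unknown trace model {model!r}")
    distances = np.where(bonded, BONDED_DISTANCE_NM, UNBONDED_DISTANCE_NM)
    return GeometricTrace.from_sequences(distances)
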