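"""Chemometric decomposition of UV-VIS titration spectra.

A titration of a constant-concentration ligand solution with increasing
amounts of DNA produces a wavelength x titration-point absorbance matrix.
For a closed two-species system (free and DNA-bound ligand) every column
is a convex combination of the two pure spectra, so the *centered* matrix
has rank one: the number of absorbing species is the centered numerical
rank plus one.  The pipeline implemented here:

1. center the matrix across titration points;
2. decompose it into eigenvectors (PCA via SVD), run twice: a first pass
   for rank/outlier diagnosis, a second pass after excluding any flagged
   outlier columns;
3. estimate the species count from the eigenvalue spectrum;
4. convert first-component scores into molar fractions of free and bound
   ligand by anchoring the score axis at the free and bound states;
5. feed the free-ligand concentrations L = x_free * c into the Scatchard
   piecewise regression of :mod:`dnabind.binding` to obtain Kd and n.

Near saturation the free-ligand fraction drops below what the spectra can
quantify; such points are excluded from the regression and, when fewer
than three well-determined points remain, the fitted Kd is flagged as an
estimation only.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .binding import (
    BindingResult,
    DEFAULT_MIN_FREE_FRACTION,
    RELIABLE_FREE_FRACTION,
    TitrationPoint,
    fit_kd_piecewise,
    scatchard_points,
    solve_free_ligand,
)
from .errors import (
    DegenerateAnchorError,
    InsufficientDataError,
    NoBindingSignalError,
    UnsupportedModelError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TitrationSeries",
    "DecompositionResult",
    "FractionSeries",
    "AnalysisConfig",
    "center_series",
    "decompose",
    "double_pca",
    "estimate_species_count",
    "scores_to_fractions",
    "analyze_titration",
]


@dataclass
class TitrationSeries:
    """Spectra matrix plus the concentration manifest of a titration.

    ``absorbance`` is wavelength x titration point; ``dna_ratios`` are
    DNA:ligand molar ratios (a leading 0 entry is the ligand-only
    reference spectrum); ``ligand_total`` (uM) is constant across points.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    ligand_total: float
    dna_ratios: np.ndarray
    absorbance_floor: float = -0.01  # tolerated baseline undershoot

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.dna_ratios = np.asarray(self.dna_ratios, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValidationError("absorbance must be a 2-D matrix")
        n_wl, n_pts = self.absorbance.shape
        if n_wl != self.wavelengths.size:
            raise ValidationError(
                f"absorbance has {n_wl} rows but {self.wavelengths.size} wavelengths"
            )
        if n_pts != self.dna_ratios.size:
            raise ValidationError(
                f"absorbance has {n_pts} columns but {self.dna_ratios.size} ratios"
            )
        if not self.ligand_total > 0:
            raise ValidationError("ligand_total must be positive")
        if np.any(self.dna_ratios < 0):
            raise ValidationError("DNA:ligand ratios must be non-negative")
        if np.any(np.diff(self.dna_ratios) <= 0):
            raise ValidationError("DNA:ligand ratios must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance values must be finite")
        if np.any(self.absorbance < self.absorbance_floor):
            raise ValidationError(
                f"absorbance below floor {self.absorbance_floor}"
            )

    @property
    def dna_totals(self) -> np.ndarray:
        """Total duplex concentration per point (uM)."""
        return self.dna_ratios * self.ligand_total

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    def windowed(self, lo: float, hi: float) -> "TitrationSeries":
        """Restrict the series to wavelengths in [lo, hi]."""
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not np.any(mask):
            raise ValidationError(f"no wavelengths in window [{lo}, {hi}]")
        return TitrationSeries(
            self.wavelengths[mask], self.absorbance[mask], self.ligand_total,
            self.dna_ratios, self.absorbance_floor,
        )


@dataclass
class DecompositionResult:
    """Eigenvector decomposition of a centered titration matrix."""

    mean_spectrum: np.ndarray
    eigenvalues: np.ndarray  # squared singular values, descending
    loadings: np.ndarray  # wavelength x component, orthonormal columns
    scores: np.ndarray  # titration point x component
    n_species: int | None = None

    def reconstruct(self) -> np.ndarray:
        """mean + scores . loadings^T, the original matrix when all
        components are kept."""
        return self.mean_spectrum[:, None] + self.loadings @ self.scores.T


@dataclass
class FractionSeries:
    """Molar fractions of free and bound ligand per titration point.

    Closure ``x_free + x_bound == 1`` holds exactly by construction;
    pre-clip extrema are retained so that out-of-range anchoring is
    visible, not silently hidden."""

    x_free: np.ndarray
    x_bound: np.ndarray
    preclip_min: float
    preclip_max: float


def center_series(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Center the absorbance matrix across titration points.

    Returns ``(centered, mean_spectrum)``; each wavelength row of
    ``centered`` has zero mean over the titration points.
    """
    if series.n_points < 2:
        raise InsufficientDataError("centering needs >= 2 titration points")
    mean_spectrum = series.absorbance.mean(axis=1)
    return series.absorbance - mean_spectrum[:, None], mean_spectrum


def decompose(centered: np.ndarray, mean_spectrum: np.ndarray | None = None
              ) -> DecompositionResult:
    """PCA of a centered matrix via singular-value decomposition.

    Eigenvalues are the squared singular values.  Sign convention: within
    each component the loading element of largest magnitude is positive,
    making scores reproducible across platforms.
    """
    centered = np.asarray(centered, dtype=float)
    if not np.all(np.isfinite(centered)):
        raise ValidationError("centered matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, j]))
        if U[pivot, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    if mean_spectrum is None:
        mean_spectrum = np.zeros(centered.shape[0])
    return DecompositionResult(
        mean_spectrum=np.asarray(mean_spectrum, dtype=float),
        eigenvalues=s ** 2,
        loadings=U,
        scores=(Vt.T * s),
    )


def double_pca(
    centered: np.ndarray,
    mean_spectrum: np.ndarray | None = None,
    outlier_factor: float = 5.0,
) -> tuple[DecompositionResult, list[int]]:
    """Two-pass PCA: diagnose outlier columns, then re-decompose without them.

    Pass 1 decomposes the full centered matrix and measures each column's
    residual from the rank-1 reconstruction; columns whose residual norm
    exceeds ``outlier_factor`` times the median are flagged.  Pass 2 runs
    the same decomposition on the remaining columns (re-centered).  With
    no outliers both passes coincide.  Returns the pass-2 result and the
    flagged column indices.
    """
    pass1 = decompose(centered, mean_spectrum)
    rank1 = pass1.loadings[:, :1] @ pass1.scores[:, :1].T
    resid = np.linalg.norm(centered - rank1, axis=0)
    med = float(np.median(resid))
    outliers = (
        [int(i) for i in np.nonzero(resid > outlier_factor * med)[0]]
        if med > 0 else []
    )
    if not outliers:
        return pass1, []
    logger.warning("double PCA pass 1 flagged outlier columns %s", outliers)
    keep = [i for i in range(centered.shape[1]) if i not in outliers]
    sub = centered[:, keep]
    sub = sub - sub.mean(axis=1, keepdims=True)
    return decompose(sub, mean_spectrum), outliers


def estimate_species_count(
    eigenvalues: np.ndarray, noise_threshold: float = 1e-2
) -> int:
    """Number of absorbing species from a centered eigenvalue spectrum.

    A closed system of s species has centered rank s - 1, so the count is
    one plus the number of eigenvalues above ``noise_threshold`` times the
    largest.  The default threshold (a component must explain at least 1%
    of the dominant variance) sits above instrument-noise eigenvalues at
    realistic signal-to-noise.  An all-zero spectrum is a single species.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0 or ev[0] <= 0:
        return 1
    if np.any(np.diff(ev) > 1e-9 * ev[0]):
        raise ValidationError("eigenvalues must be sorted descending")
    return int(np.sum(ev > noise_threshold * ev[0])) + 1


def _model_bound_fraction(ratios: np.ndarray, kappa: float) -> np.ndarray:
    """Bound fraction of a 1:1 two-species titration at DNA:ligand ratios.

    ``kappa`` is Kd divided by the total ligand concentration; the bound
    fraction depends on Kd and c only through this ratio.
    """
    out = np.empty(ratios.size)
    for i, r in enumerate(ratios):
        L_over_c = solve_free_ligand(1.0, float(r), kappa, 1.0)
        out[i] = 1.0 - L_over_c
    return out


def scores_to_fractions(
    scores: np.ndarray,
    ratios: np.ndarray,
    anchor_mode: str = "fit",
) -> FractionSeries:
    """Convert first-component scores to free/bound molar fractions.

    The score of each titration point is affine in the bound fraction, so
    two anchors fix the axis: ``s_free`` (score of the pure free ligand)
    and ``s_bound`` (score at full binding).  ``s_free`` is the score of
    the ratio-0 point when present, otherwise extrapolated from the model
    fit below.  ``s_bound`` per ``anchor_mode``:

    - ``"saturation"``: score of the largest-ratio point.  Exact only if
      that point is fully bound; for weak binders it is not, which biases
      every fraction (a caveat is logged).
    - ``"fit"`` (default): a 1:1 two-species binding profile is
      least-squares fitted to the scores over a scalar auxiliary Kd/c
      parameter, and ``s_bound`` is the fitted score at full binding.
      The auxiliary parameter only anchors the axis; the reported Kd and
      n still come from the Scatchard regression downstream.
    """
    s = np.asarray(scores, dtype=float).ravel()
    ratios = np.asarray(ratios, dtype=float).ravel()
    if s.size != ratios.size:
        raise ValidationError("scores and ratios must have equal length")
    if s.size < 2:
        raise InsufficientDataError("need >= 2 titration points")
    if np.ptp(s) == 0:
        raise DegenerateAnchorError("scores are constant across points")

    has_ref = ratios[0] == 0.0

    if anchor_mode == "saturation":
        if not has_ref:
            raise ValidationError(
                "saturation anchoring requires a ratio-0 reference point"
            )
        s_free = s[0]
        s_bound = s[-1]
        logger.warning(
            "saturation anchoring assumes the largest-ratio point is fully "
            "bound; fractions are biased if binding is incomplete there"
        )
    elif anchor_mode == "fit":
        def lack_of_fit(log10_kappa: float) -> float:
            m = _model_bound_fraction(ratios, 10.0 ** log10_kappa)
            A = np.column_stack([np.ones_like(m), m])
            coef, *_ = np.linalg.lstsq(A, s, rcond=None)
            return float(np.sum((s - A @ coef) ** 2))

        grid = np.linspace(-5.0, 1.5, 27)
        best = min(grid, key=lack_of_fit)
        res = minimize_scalar(
            lack_of_fit, bounds=(best - 0.3, best + 0.3), method="bounded",
            options={"xatol": 1e-6},
        )
        kappa = 10.0 ** float(res.x)
        m = _model_bound_fraction(ratios, kappa)
        A = np.column_stack([np.ones_like(m), m])
        (alpha, beta), *_ = np.linalg.lstsq(A, s, rcond=None)
        s_free = s[0] if has_ref else float(alpha)
        s_bound = float(alpha + beta)
    else:
        raise ValidationError(f"unknown anchor_mode {anchor_mode!r}")

    if s_bound == s_free:
        raise DegenerateAnchorError("bound and free anchors coincide")

    x_bound = (s - s_free) / (s_bound - s_free)
    preclip_min, preclip_max = float(x_bound.min()), float(x_bound.max())
    if preclip_min < -1e-9 or preclip_max > 1 + 1e-9:
        logger.info(
            "fractions clipped to [0,1]; pre-clip range [%.4f, %.4f]",
            preclip_min, preclip_max,
        )
    x_bound = np.clip(x_bound, 0.0, 1.0)
    if has_ref:
        x_bound[0] = 0.0  # the ligand-only reference is free by definition
    return FractionSeries(
        x_free=1.0 - x_bound,
        x_bound=x_bound,
        preclip_min=preclip_min,
        preclip_max=preclip_max,
    )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the end-to-end titration analysis."""

    window: tuple[float, float] | None = None  # wavelength window (nm)
    anchor_mode: str = "fit"
    species_threshold: float = 1e-2  # eigenvalue fraction for species count
    min_free_fraction: float = DEFAULT_MIN_FREE_FRACTION
    reliable_free_fraction: float = RELIABLE_FREE_FRACTION


def analyze_titration(
    series: TitrationSeries, config: AnalysisConfig | None = None
) -> BindingResult:
    """Full chemometric chain from spectra matrix to fitted Kd and n.

    center -> double PCA -> species count -> score anchoring -> molar
    fractions -> L = x_free * c -> occupancy v = (c - L)/M -> Scatchard
    -> piecewise regression.  Aborts with a diagnostic unless exactly two
    spectral species are found.  The result's ``provenance`` records the
    species count, fractions, excluded points and resolved configuration.
    """
    cfg = config or AnalysisConfig()
    work = series.windowed(*cfg.window) if cfg.window else series

    centered, mean_spectrum = center_series(work)
    signal = np.linalg.norm(centered)
    if signal <= 1e-10 * max(np.linalg.norm(work.absorbance), 1.0):
        raise NoBindingSignalError(
            "spectra are invariant across the titration: single species, "
            "no binding signal"
        )
    decomp, outlier_cols = double_pca(centered, mean_spectrum)
    n_species = estimate_species_count(decomp.eigenvalues, cfg.species_threshold)
    decomp.n_species = n_species
    if n_species == 1:
        raise NoBindingSignalError(
            "spectra are invariant across the titration: single species, "
            "no binding signal"
        )
    if n_species != 2:
        raise UnsupportedModelError(
            f"estimated {n_species} absorbing species; only the two-species "
            "(free/bound ligand) pathway is supported"
        )

    ratios = np.delete(work.dna_ratios, outlier_cols) if outlier_cols \
        else work.dna_ratios
    fractions = scores_to_fractions(decomp.scores[:, 0], ratios, cfg.anchor_mode)

    c = work.ligand_total
    points: list[TitrationPoint] = []
    n_reliable = 0
    for ratio, x_free in zip(ratios, fractions.x_free):
        if ratio <= 0:
            continue  # ligand-only reference: no host, occupancy undefined
        points.append(TitrationPoint(c=c, M=ratio * c, L=float(x_free) * c))
        if x_free >= cfg.reliable_free_fraction:
            n_reliable += 1

    sc = scatchard_points(points, min_free_fraction=cfg.min_free_fraction)
    if len(sc) < 2:
        raise InsufficientDataError(
            f"only {len(sc)} usable sub-saturation Scatchard points"
        )
    result = fit_kd_piecewise(sc, n_reliable_points=n_reliable)
    result.provenance = {
        "n_species": n_species,
        "x_free": fractions.x_free.tolist(),
        "x_bound": fractions.x_bound.tolist(),
        "preclip_range": [fractions.preclip_min, fractions.preclip_max],
        "excluded_columns": outlier_cols,
        "n_scatchard_points": len(sc),
        "n_reliable_points": n_reliable,
        "config": asdict(cfg),
    }
    logger.info(
        "titration analysis: Kd=%.4g uM, n=%.3g, %d Scatchard points, "
        "estimate_flag=%s", result.Kd, result.n, len(sc), result.estimate_flag,
    )
    return result
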