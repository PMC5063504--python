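"""Emission spectra containers and parametric reference shapes.

A fluorometer emission scan is represented by :class:`Spectrum`: an
ascending wavelength grid (nm) with one intensity per grid point (a.u.),
plus the excitation wavelength and free-form condition/construct labels.

Donor (Cerulean-like, emission peak 475 nm) and acceptor (Venus-like,
emission peak ~525 nm) reference emission shapes are generated
parametrically by :func:`make_reference_spectra`.  Real fluorescent-protein
emission spectra are right-skewed, so the shapes are Gaussians whose width
grows linearly on the long-wavelength side of the peak — smooth, maximal
exactly at the nominal peak, with a long red tail.  The exact shape is
immaterial to the downstream analysis, which only assumes linear mixing of
two known, linearly independent shapes.

Direct (non-FRET) excitation of the acceptor is described by a relative
efficiency profile over excitation wavelength, normalized to 1 at the
acceptor's direct-excitation maximum (515 nm for Venus-like acceptors) and
decaying toward shorter wavelengths.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "DirectExcitationProfile",
    "ReferenceSpectra",
    "make_reference_spectra",
]


@dataclass
class Spectrum:
    """One emission scan: wavelength grid + intensities + metadata.

    Parameters
    ----------
    wavelength_nm : array
        Strictly increasing wavelength grid in nm.
    intensity : array
        Fluorescence intensity (a.u.), same length as the grid; must be finite.
    excitation_nm : float
        Excitation wavelength of the scan, nm.
    condition, construct_id : str
        Free-form labels (e.g. ``"Ca-saturated"``, ``"CTV-TnC WT"``).
    ground_truth : dict or None
        For simulated scans: the generating amplitudes
        (``f_don``, ``f_acc_fret``, ``f_acc_direct``, ``f_r``), kept for
        testing only — the analysis never reads it.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    condition: str = ""
    construct_id: str = ""
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("wavelength and intensity must be 1-D")
        if self.wavelength_nm.size != self.intensity.size:
            raise ValueError(
                f"length mismatch: {self.wavelength_nm.size} wavelengths vs "
                f"{self.intensity.size} intensities"
            )
        if self.wavelength_nm.size >= 2 and not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            bad = int(np.flatnonzero(~np.isfinite(self.intensity))[0])
            raise ValueError(f"non-finite intensity at index {bad}")

    def __len__(self) -> int:
        return self.wavelength_nm.size


@dataclass(frozen=True)
class DirectExcitationProfile:
    """Relative direct-excitation efficiency of the acceptor vs lambda_ex.

    Log-normal in excitation wavelength: ``exp(-(ln(x/peak))^2 / (2 s^2))``,
    equal to 1.0 at the peak (515 nm default) and monotonically decreasing
    away from it.  The default log-width 0.08 puts the 433 nm efficiency at
    ~0.10 of the maximum, i.e. direct excitation is a minor correction at
    donor excitation wavelengths and smaller still at shorter lambda_ex.
    """

    peak_nm: float = 515.0
    log_width: float = 0.08
    domain_nm: tuple[float, float] = (390.0, 560.0)

    def __call__(self, excitation_nm: float) -> float:
        lo, hi = self.domain_nm
        x = float(excitation_nm)
        if not lo <= x <= hi:
            raise ValueError(
                f"excitation {x} nm outside direct-excitation profile domain "
                f"[{lo}, {hi}] nm"
            )
        z = math.log(x / self.peak_nm) / self.log_width
        return math.exp(-0.5 * z * z)


def _skewed_peak(grid: np.ndarray, peak: float, width: float, skew: float) -> np.ndarray:
    """Unit-max peak: Gaussian whose SD grows linearly past the peak.

    sigma(lambda) = width            for lambda <= peak
                  = width + skew*(lambda - peak)   for lambda > peak
    """
    sigma = np.where(grid > peak, width + skew * (grid - peak), width)
    z = (grid - peak) / sigma
    return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class ReferenceSpectra:
    """Donor/acceptor reference emission shapes on a shared wavelength grid.

    Both shapes are nonnegative with grid maximum exactly 1.0.  The
    direct-excitation profile and the two read-out wavelengths (donor
    emission peak, acceptor peak-read wavelength) travel with the shapes so
    that every analysis step uses a single consistent reference set.
    """

    wavelength_nm: np.ndarray
    donor_emission: np.ndarray
    acceptor_emission: np.ndarray
    direct_profile: DirectExcitationProfile = field(default_factory=DirectExcitationProfile)
    donor_peak_nm: float = 475.0
    acceptor_peak_nm: float = 515.0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        d = np.asarray(self.donor_emission, dtype=float)
        a = np.asarray(self.acceptor_emission, dtype=float)
        if not (w.shape == d.shape == a.shape):
            raise ValueError("donor/acceptor shapes must share the wavelength grid")
        for name, s in (("donor", d), ("acceptor", a)):
            if np.any(s < 0):
                raise ValueError(f"{name} emission shape has negative values")
            if not math.isclose(float(s.max()), 1.0, rel_tol=0, abs_tol=1e-12):
                raise ValueError(f"{name} emission shape max is {s.max()}, expected 1.0")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "donor_emission", d)
        object.__setattr__(self, "acceptor_emission", a)

    def gram_condition(self) -> float:
        """Condition number of the 2x2 Gram matrix of the two shapes."""
        m = np.column_stack([self.donor_emission, self.acceptor_emission])
        return float(np.linalg.cond(m.T @ m))


def make_reference_spectra(
    donor_peak_nm: float = 475.0,
    acceptor_peak_nm: float = 525.0,
    donor_width_nm: float = 14.0,
    acceptor_width_nm: float = 12.0,
    donor_skew: float = 0.35,
    acceptor_skew: float = 0.30,
    wavelength_start_nm: float = 445.0,
    wavelength_stop_nm: float = 610.0,
    wavelength_step_nm: float = 1.0,
    acceptor_read_nm: float = 515.0,
    direct_profile: DirectExcitationProfile | None = None,
) -> ReferenceSpectra:
    """Build parametric donor/acceptor reference emission shapes.

    The default grid is the fluorometer scan window 445–610 nm at 1 nm.
    Peaks must lie inside the grid; widths must exceed the grid step (a
    narrower peak cannot be represented and would degenerate to a spike).
    Identical donor and acceptor parameters are rejected because the
    resulting unmixing design would be singular.

    Note the acceptor *emission* peak (525 nm for Venus-like proteins) is
    distinct from the acceptor *peak-read* wavelength (``acceptor_read_nm``,
    515 nm), which is where titration-series peak reads are taken; both are
    exposed rather than conflated.
    """
    if wavelength_step_nm <= 0:
        raise ValueError("wavelength step must be > 0")
    grid = np.arange(
        wavelength_start_nm, wavelength_stop_nm + wavelength_step_nm / 2, wavelength_step_nm
    )
    for name, peak in (("donor", donor_peak_nm), ("acceptor", acceptor_peak_nm)):
        if not grid[0] <= peak <= grid[-1]:
            raise ValueError(f"{name} peak {peak} nm outside grid [{grid[0]}, {grid[-1]}] nm")
    for name, width in (("donor", donor_width_nm), ("acceptor", acceptor_width_nm)):
        if width <= 0 or width < wavelength_step_nm:
            raise ValueError(
                f"{name} width {width} nm is degenerate (must exceed grid step "
                f"{wavelength_step_nm} nm)"
            )
    if (donor_peak_nm, donor_width_nm, donor_skew) == (
        acceptor_peak_nm,
        acceptor_width_nm,
        acceptor_skew,
    ):
        raise ValueError(
            "identical donor and acceptor shape parameters: unmixing would be singular"
        )

    donor = _skewed_peak(grid, donor_peak_nm, donor_width_nm, donor_skew)
    acceptor = _skewed_peak(grid, acceptor_peak_nm, acceptor_width_nm, acceptor_skew)
    donor = donor / donor.max()
    acceptor = acceptor / acceptor.max()
    return ReferenceSpectra(
        wavelength_nm=grid,
        donor_emission=donor,
        acceptor_emission=acceptor,
        direct_profile=direct_profile or DirectExcitationProfile(),
        donor_peak_nm=donor_peak_nm,
        acceptor_peak_nm=acceptor_read_nm,
    )
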