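"""Spectral unmixing and the FRET-ratio statistic.

Each emission scan is modeled as a linear mix of the donor and acceptor
reference emission shapes; ordinary least squares over the scan window
gives the component amplitudes F_Don and F_Acc.  The acceptor amplitude
splits into a FRET-driven part and a direct-excitation part,

    F_Acc = F_AccFRET + F_AccDirect,

and the direct part is estimated from an acceptor-only control: the ratio
r(lambda_ex) of the control's acceptor amplitude at lambda_ex to its
amplitude under maximal direct excitation (515 nm) scales the sample's own
515 nm acceptor amplitude.  The FRET ratio

    F_R = F_AccFRET / F_Don

is amplitude-invariant, hence independent of excitation wavelength and
lamp/PMT settings.  An end-point experiment (chelated -> saturating
cation -> re-chelated) is summarized by per-condition means of F_R over
the excitation ladder and the end-point signal

    dF_R = mean over lambda_ex of [F_R(cation) - (F_R(initial)+F_R(final))/2],

with the initial/final difference serving as a reversibility diagnostic.

Amplitudes are deliberately unconstrained: under noise a truly-zero
component should scatter around zero rather than pile up at it, so small
negative estimates are reported (with a warning flag) instead of clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .simulate import EndpointDataset
from .spectra import ReferenceSpectra, Spectrum

__all__ = [
    "Amplitudes",
    "UnmixResult",
    "EndpointResult",
    "unmix",
    "direct_excitation_fraction",
    "correct_direct",
    "fret_ratio",
    "unmix_scan",
    "analyze_endpoint",
    "peak_read",
]

COND_LIMIT = 1e8  # design-matrix condition number above which unmixing refuses


class Amplitudes(NamedTuple):
    f_don: float
    f_acc: float
    residual_ss: float
    negative: bool  # any amplitude came out below zero


@dataclass
class UnmixResult:
    """Full per-scan decomposition; F_Acc = F_AccFRET + F_AccDirect holds
    by construction."""

    f_don: float
    f_acc: float
    f_acc_direct: float
    residual_ss: float
    excitation_nm: float
    condition: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def f_acc_fret(self) -> float:
        return self.f_acc - self.f_acc_direct

    @property
    def f_r(self) -> float:
        return fret_ratio(self.f_acc_fret, self.f_don)


def _design(spectrum: Spectrum, refs: ReferenceSpectra) -> np.ndarray:
    grid = spectrum.wavelength_nm
    rgrid = refs.wavelength_nm
    if grid[0] < rgrid[0] or grid[-1] > rgrid[-1]:
        raise ValueError(
            "spectrum grid extends beyond the reference grid: extrapolation of "
            "reference shapes is not allowed"
        )
    donor = np.interp(grid, rgrid, refs.donor_emission)
    acceptor = np.interp(grid, rgrid, refs.acceptor_emission)
    design = np.column_stack([donor, acceptor])
    cond = np.linalg.cond(design)
    if cond > COND_LIMIT:
        raise ValueError(
            f"collinear reference shapes (design condition number {cond:.3g}): "
            "donor and acceptor references are not distinguishable on this grid"
        )
    return design


def unmix(spectrum: Spectrum, refs: ReferenceSpectra) -> Amplitudes:
    """Least-squares decomposition of a scan into donor/acceptor amplitudes.

    Returns the unconstrained global least-squares solution of
    ``intensity ~ f_don * donor + f_acc * acceptor`` together with the
    residual sum of squares.  Negative amplitudes are reported as-is with
    the ``negative`` flag set (and a warning).
    """
    design = _design(spectrum, refs)
    coef, res, _, _ = np.linalg.lstsq(design, spectrum.intensity, rcond=None)
    residual = float(res[0]) if res.size else float(
        np.sum((spectrum.intensity - design @ coef) ** 2)
    )
    f_don, f_acc = float(coef[0]), float(coef[1])
    # below-zero at floating-point scale is not "negative": only flag
    # amplitudes meaningfully under zero relative to the scan's scale
    tol = 1e-9 * max(abs(f_don), abs(f_acc), 1.0)
    negative = f_don < -tol or f_acc < -tol
    if negative:
        # a zero-amplitude component scatters around zero under noise, so
        # warn out loud only when the estimate is negative beyond the
        # scan's own residual noise; the flag is set either way
        noise_floor = 3.0 * np.sqrt(residual / max(len(spectrum) - 2, 1))
        if f_don < -noise_floor or f_acc < -noise_floor:
            warnings.warn(
                f"negative unmixed amplitude (f_don={f_don:.4g}, f_acc={f_acc:.4g}); "
                "reported unclipped"
            )
    return Amplitudes(f_don=f_don, f_acc=f_acc, residual_ss=residual, negative=negative)


def direct_excitation_fraction(
    control_at_lambda: Spectrum,
    control_at_direct_max: Spectrum,
    refs: ReferenceSpectra,
) -> float:
    """Direct-excitation ratio r(lambda_ex) from acceptor-only controls.

    r = (unmixed acceptor amplitude of the control at lambda_ex) /
        (unmixed acceptor amplitude of the control at 515 nm).
    Expected in [0, 1]; an unusable (non-positive) denominator raises.
    """
    num = unmix(control_at_lambda, refs).f_acc
    den = unmix(control_at_direct_max, refs).f_acc
    if den <= 0:
        raise ValueError(
            f"acceptor-only control at direct-excitation maximum has amplitude "
            f"{den:.4g} <= 0: unusable control"
        )
    return num / den


def correct_direct(f_acc: float, sample_acc_at_direct_max: float, r: float) -> float:
    """Remove the direct-excitation component from the acceptor amplitude.

    F_AccDirect for the sample at lambda_ex is the sample's own 515 nm
    acceptor amplitude scaled by the control-derived ratio r(lambda_ex);
    F_AccFRET = F_Acc - r * (sample amplitude at 515 nm).
    """
    if r < 0:
        raise ValueError("direct-excitation ratio r must be >= 0")
    if not (np.isfinite(f_acc) and np.isfinite(sample_acc_at_direct_max)):
        raise ValueError("non-finite input amplitude")
    return f_acc - r * sample_acc_at_direct_max


def fret_ratio(f_acc_fret: float, f_don: float) -> float:
    """F_R = F_AccFRET / F_Don; requires a positive donor amplitude."""
    if f_don <= 0:
        raise ValueError(f"donor amplitude {f_don:.4g} <= 0: uninterpretable scan")
    return f_acc_fret / f_don


def unmix_scan(
    spectrum: Spectrum,
    refs: ReferenceSpectra,
    sample_acc_at_direct_max: float,
    r: float,
    noise_se: float = 0.0,
) -> UnmixResult:
    """Full decomposition of one sample scan given its direct-excitation
    normalization (sample 515 nm amplitude and control ratio r)."""
    amp = unmix(spectrum, refs)
    f_acc_direct = r * sample_acc_at_direct_max
    flags = []
    if amp.negative:
        flags.append("negative_amplitude")
    f_acc_fret = amp.f_acc - f_acc_direct
    if noise_se > 0 and f_acc_fret < -3.0 * noise_se:
        flags.append("strongly_negative_fret")
    return UnmixResult(
        f_don=amp.f_don,
        f_acc=amp.f_acc,
        f_acc_direct=f_acc_direct,
        residual_ss=amp.residual_ss,
        excitation_nm=spectrum.excitation_nm,
        condition=spectrum.condition,
        flags=flags,
    )


@dataclass
class EndpointResult:
    """Per-condition F_R summary and the end-point signal dF_R."""

    condition_order: tuple[str, str, str]
    mean_fr: dict[str, float]
    se_fr: dict[str, float]
    delta_fr: float
    delta_fr_se: float
    reversibility_gap: float
    reversibility_gap_se: float
    reversible: bool
    per_scan: list[UnmixResult] = field(default_factory=list)
    excluded_excitations: list[float] = field(default_factory=list)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return m, se


def analyze_endpoint(
    dataset: EndpointDataset, refs: ReferenceSpectra | None = None
) -> EndpointResult:
    """Run the full end-point analysis on a three-condition dataset.

    For every excitation wavelength with an acceptor-only control, each
    condition's scan is unmixed, corrected for direct excitation using the
    per-condition 515 nm sample scan, and converted to F_R.  Excitations
    lacking a control are excluded with a warning; a missing condition is
    an error.  The reversibility diagnostic compares initial and final
    conditions; the dataset is flagged non-reversible when the gap exceeds
    3x its standard error.
    """
    refs = refs if refs is not None else dataset.references
    labels = dataset.condition_order
    missing = [c for c in labels if c not in dataset.scans]
    if missing:
        raise ValueError(f"missing condition(s) {missing} in end-point dataset")

    max_nm = refs.acceptor_peak_nm
    if max_nm not in dataset.control_scans:
        raise ValueError(
            f"no acceptor-only control at the direct-excitation maximum ({max_nm} nm)"
        )
    control_max = dataset.control_scans[max_nm]

    sample_at_max = {}
    for label in labels:
        if label not in dataset.sample_direct_scans:
            raise ValueError(f"missing {max_nm} nm sample scan for condition {label!r}")
        sample_at_max[label] = unmix(dataset.sample_direct_scans[label], refs).f_acc

    excitations = sorted(
        {ex for label in labels for ex in dataset.scans[label]}, reverse=True
    )
    fr: dict[str, list[float]] = {label: [] for label in labels}
    per_scan: list[UnmixResult] = []
    excluded: list[float] = []
    for ex in excitations:
        if ex not in dataset.control_scans:
            warnings.warn(f"no acceptor-only control at {ex} nm: excitation excluded")
            excluded.append(ex)
            continue
        r = direct_excitation_fraction(dataset.control_scans[ex], control_max, refs)
        for label in labels:
            if ex not in dataset.scans[label]:
                raise ValueError(f"condition {label!r} lacks a scan at {ex} nm")
            result = unmix_scan(dataset.scans[label][ex], refs, sample_at_max[label], r)
            per_scan.append(result)
            fr[label].append(result.f_r)

    used = [ex for ex in excitations if ex not in excluded]
    if not used:
        raise ValueError("no excitation wavelength has a usable control")

    mean_fr, se_fr = {}, {}
    for label in labels:
        mean_fr[label], se_fr[label] = _mean_se(np.asarray(fr[label]))

    init, cation, final = labels
    deltas = np.asarray(fr[cation]) - 0.5 * (np.asarray(fr[init]) + np.asarray(fr[final]))
    delta_fr, delta_fr_se = _mean_se(deltas)
    gap = abs(mean_fr[init] - mean_fr[final])
    gap_se = float(np.hypot(se_fr[init], se_fr[final]))
    reversible = gap <= 3.0 * gap_se if gap_se > 0 else gap == 0.0

    return EndpointResult(
        condition_order=labels,
        mean_fr=mean_fr,
        se_fr=se_fr,
        delta_fr=delta_fr,
        delta_fr_se=delta_fr_se,
        reversibility_gap=gap,
        reversibility_gap_se=gap_se,
        reversible=reversible,
        per_scan=per_scan,
        excluded_excitations=excluded,
    )


def peak_read(
    spectrum: Spectrum, donor_peak_nm: float = 475.0, acceptor_peak_nm: float = 515.0
) -> tuple[float, float]:
    """Intensities at the grid points nearest the two read-out wavelengths.

    The simpler alternative to full unmixing used for titration series;
    note the acceptor read at 515 nm contains donor-emission cross-talk,
    which is why unmixing is the default elsewhere.  Nearest-grid-point
    ties resolve to the lower wavelength.
    """
    grid = spectrum.wavelength_nm
    for name, nm in (("donor", donor_peak_nm), ("acceptor", acceptor_peak_nm)):
        if not grid[0] <= nm <= grid[-1]:
            raise ValueError(f"{name} read wavelength {nm} nm outside scan window")

    def nearest(nm: float) -> int:
        d = np.abs(grid - nm)
        return int(np.argmin(d))  # argmin takes the first (lower-wavelength) tie

    return (
        float(spectrum.intensity[nearest(donor_peak_nm)]),
        float(spectrum.intensity[nearest(acceptor_peak_nm)]),
    )
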