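"""Synthetic fluorometer: seeded generators for every pipeline input.

Emulates the spectrofluorometer protocol used to characterize TnC-based
FRET sensors: emission scans over 445–610 nm at a ladder of excitation
wavelengths (433 down to 400 nm), a three-condition end-point protocol
(chelated -> saturating Ca2+ -> re-chelated), acceptor-only control scans,
full-range pX titration series, and Gaussian sedimentation-coefficient
distributions.  Every generated object carries its ground truth so the
analysis stages can be tested without instrument data.

Generative model for one scan (linear mixing, the only photophysics the
downstream analysis assumes):

    I(lambda) = F_Don * donor(lambda)
              + (F_R * F_Don + F_AccDirect) * acceptor(lambda)
              + Gaussian noise

where F_AccDirect = (direct amplitude at 515 nm excitation) x
direct-excitation profile(lambda_ex).  Donor excitation efficiency varies
with lambda_ex but only scales total brightness; the FRET ratio F_R is a
ratio and cancels it, which is exactly the lambda_ex-invariance the
analysis exploits.  Noise is additive i.i.d. Gaussian per wavelength
(PMT readout at fixed voltage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import ConstructDesign, SiteContributions, predict
from .fitting import (
    GaussianPeak,
    TitrationSeries,
    double_hill_model,
    gaussian_peak_model,
    hill_force_model,
    single_hill_model,
)
from .spectra import ReferenceSpectra, Spectrum, make_reference_spectra

__all__ = [
    "SimulationConfig",
    "EndpointDataset",
    "DEFAULT_EXCITATIONS",
    "simulate_spectrum",
    "simulate_acceptor_only",
    "simulate_endpoint_experiment",
    "simulate_titration",
    "simulate_auc_distribution",
    "donor_excitation_scale",
]

#: Excitation-wavelength ladder of the end-point protocol (nm).
DEFAULT_EXCITATIONS: tuple[float, ...] = (433, 424, 420, 418, 414, 410, 408, 404, 400)

_PROTOCOLS = {
    # titrant ion, background ion (bound in conditions 1 and 3), condition labels
    "Ca-in-EDTA": ("Ca", None, ("chelated", "Ca-saturated", "re-chelated")),
    "Ca-in-Mg/EGTA": ("Ca", "Mg", ("Mg/EGTA", "Ca-saturated", "Mg/EGTA-re")),
    "Mg-in-EDTA": ("Mg", None, ("chelated", "Mg-saturated", "re-chelated")),
}
_MG_SITES = frozenset({"III", "IV"})


@dataclass
class SimulationConfig:
    """Parameters of a simulated fluorometer run.

    ``mode`` selects the titration generative model: ``"hill"`` evaluates a
    Hill-type response curve given in ``model_params`` (see
    :func:`simulate_titration`); ``"site-additive"`` builds the response
    from per-site occupancies and contributions.  Exactly the block named
    by ``mode`` must be supplied.

    ``donor_amplitude`` is the donor-channel scale at the reference
    excitation (433 nm); ``direct_at_max`` is the acceptor amplitude under
    maximal direct excitation (515 nm) for the same sample; ``resting_fr``
    is the cation-independent FRET-ratio level of the apo sensor.
    """

    seed: int = 0
    noise_sd: float = 0.0
    wavelength_start_nm: float = 445.0
    wavelength_stop_nm: float = 610.0
    wavelength_step_nm: float = 1.0
    excitation_list: tuple[float, ...] = DEFAULT_EXCITATIONS
    mode: str = "hill"
    model_params: dict | None = None
    donor_amplitude: float = 100.0
    direct_at_max: float = 10.0
    resting_fr: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.excitation_list:
            raise ValueError("excitation_list must be nonempty")
        if self.wavelength_step_nm <= 0:
            raise ValueError("wavelength step must be > 0")
        if self.mode not in ("hill", "site-additive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.donor_amplitude <= 0:
            raise ValueError("donor_amplitude must be > 0")

    def wavelength_grid(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start_nm,
            self.wavelength_stop_nm + self.wavelength_step_nm / 2,
            self.wavelength_step_nm,
        )

    def make_references(self) -> ReferenceSpectra:
        return make_reference_spectra(
            wavelength_start_nm=self.wavelength_start_nm,
            wavelength_stop_nm=self.wavelength_stop_nm,
            wavelength_step_nm=self.wavelength_step_nm,
        )


def donor_excitation_scale(excitation_nm: float) -> float:
    """Relative donor brightness vs excitation wavelength.

    A single scalar per lambda_ex (1.0 at 433 nm falling to 0.55 at
    400 nm): brightness drops off the donor absorption peak, but since the
    FRET ratio is amplitude-invariant the exact curve is inconsequential.
    """
    lo, hi = 400.0, 433.0
    x = min(max(excitation_nm, lo), hi)
    return 0.55 + 0.45 * (x - lo) / (hi - lo)


def _interp_refs(refs: ReferenceSpectra, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if grid[0] < refs.wavelength_nm[0] or grid[-1] > refs.wavelength_nm[-1]:
        raise ValueError("simulation grid extends beyond reference spectra grid")
    return (
        np.interp(grid, refs.wavelength_nm, refs.donor_emission),
        np.interp(grid, refs.wavelength_nm, refs.acceptor_emission),
    )


def simulate_spectrum(
    f_r: float,
    donor_amplitude: float,
    excitation_nm: float,
    refs: ReferenceSpectra,
    acceptor_direct_amount: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    condition: str = "",
    construct_id: str = "",
) -> Spectrum:
    """Generate one emission scan with known donor/acceptor amplitudes.

    ``acceptor_direct_amount`` is the directly-excited acceptor amplitude
    *at this excitation wavelength* (i.e. already scaled by the
    direct-excitation profile).  The generating amplitudes are attached as
    ``ground_truth``.
    """
    if donor_amplitude <= 0:
        raise ValueError("donor_amplitude must be > 0")
    if f_r < 0:
        raise ValueError("f_r must be >= 0")
    refs.direct_profile(excitation_nm)  # validates the excitation domain
    grid = refs.wavelength_nm
    donor, acceptor = refs.donor_emission, refs.acceptor_emission
    f_acc_fret = f_r * donor_amplitude
    intensity = (
        donor_amplitude * donor + (f_acc_fret + acceptor_direct_amount) * acceptor
    )
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(
        wavelength_nm=grid.copy(),
        intensity=intensity,
        excitation_nm=float(excitation_nm),
        condition=condition,
        construct_id=construct_id,
        ground_truth={
            "f_don": donor_amplitude,
            "f_acc_fret": f_acc_fret,
            "f_acc_direct": acceptor_direct_amount,
            "f_r": f_r,
        },
    )


def simulate_acceptor_only(
    excitation_nm: float,
    amount_at_direct_max: float,
    refs: ReferenceSpectra,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    condition: str = "",
    construct_id: str = "acceptor-only",
) -> Spectrum:
    """Acceptor-only control scan: pure acceptor shape scaled by the
    direct-excitation profile at ``excitation_nm``."""
    if amount_at_direct_max <= 0:
        raise ValueError("amount_at_direct_max must be > 0")
    amount = amount_at_direct_max * refs.direct_profile(excitation_nm)
    intensity = amount * refs.acceptor_emission
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.size)
    return Spectrum(
        wavelength_nm=refs.wavelength_nm.copy(),
        intensity=intensity,
        excitation_nm=float(excitation_nm),
        condition=condition,
        construct_id=construct_id,
        ground_truth={"f_don": 0.0, "f_acc_fret": 0.0, "f_acc_direct": amount, "f_r": 0.0},
    )


@dataclass
class EndpointDataset:
    """Everything one end-point experiment produces.

    ``scans[condition][lambda_ex]`` are the sample emission scans;
    ``sample_direct_scans[condition]`` the per-condition 515 nm-excitation
    scans of the sample (for the direct-excitation normalization);
    ``control_scans[lambda_ex]`` the acceptor-only controls, including the
    515 nm entry.  ``condition_order`` is (initial, cation, final).
    ``true_fr``/``true_delta_fr`` are the generator's ground truth.
    """

    construct: ConstructDesign
    protocol: str
    condition_order: tuple[str, str, str]
    scans: dict[str, dict[float, Spectrum]]
    sample_direct_scans: dict[str, Spectrum]
    control_scans: dict[float, Spectrum]
    references: ReferenceSpectra
    true_fr: dict[str, float] = field(default_factory=dict)
    true_delta_fr: float = 0.0


def _condition_fr(
    config: SimulationConfig,
    construct: ConstructDesign,
    occupied_by: dict[str, SiteContributions],
) -> float:
    """Resting level plus contributions of occupied active sites, per ion."""
    fr = config.resting_fr
    for ion_contrib in occupied_by.values():
        fr += predict(ion_contrib, construct)
    return fr


def simulate_endpoint_experiment(
    construct: ConstructDesign,
    contributions: SiteContributions | dict[str, SiteContributions],
    ion_protocol: str,
    config: SimulationConfig,
    refs: ReferenceSpectra | None = None,
) -> EndpointDataset:
    """Simulate the three-condition end-point protocol for one construct.

    Per-condition true F_R follows the additive site model: the resting
    level plus the contributions of the sites occupied in that condition
    (all active sites for the titrant cation; sites III/IV for a Mg2+
    background; none when chelated).  Conditions 1 and 3 share the same
    true F_R, i.e. reversibility is built in.  The true end-point signal
    dF_R = F_R(cation) - F_R(chelated) therefore equals the sum of the
    active sites' contributions.

    ``contributions``: a single :class:`SiteContributions` whose ion
    matches the titrant, or a ``{ion: SiteContributions}`` mapping (both
    "Ca" and "Mg" are required for the Ca-in-Mg/EGTA protocol).
    """
    if ion_protocol not in _PROTOCOLS:
        raise ValueError(f"unknown protocol {ion_protocol!r}; valid: {sorted(_PROTOCOLS)}")
    titrant, background, labels = _PROTOCOLS[ion_protocol]

    if isinstance(contributions, SiteContributions):
        contribs = {contributions.ion: contributions}
    else:
        contribs = dict(contributions)
    needed = {titrant} | ({background} if background else set())
    missing = needed - set(contribs)
    if missing:
        raise ValueError(
            f"protocol {ion_protocol!r} needs contributions for ion(s) {sorted(missing)}"
        )
    for ion, c in contribs.items():
        if c.ion != ion:
            raise ValueError(f"contributions labeled {c.ion!r} supplied under key {ion!r}")

    refs = refs if refs is not None else config.make_references()
    rng = np.random.default_rng(config.seed)

    # Occupancy per condition.  Mg occupies only the C-domain sites; the
    # titrant at saturation occupies every active site it can bind.
    def restrict(ion: str, c: SiteContributions) -> SiteContributions:
        if ion == "Mg":
            kept = {s: v for s, v in c.contributions.items() if s in _MG_SITES}
            return SiteContributions(ion="Mg", contributions=kept, baseline=c.baseline)
        return c

    chelated: dict[str, SiteContributions] = (
        {background: restrict(background, contribs[background])} if background else {}
    )
    saturated = {titrant: restrict(titrant, contribs[titrant])}

    occupancy = [chelated, saturated, chelated]
    true_fr = {
        label: _condition_fr(config, construct, occ)
        for label, occ in zip(labels, occupancy)
    }

    scans: dict[str, dict[float, Spectrum]] = {}
    sample_direct: dict[str, Spectrum] = {}
    for label in labels:
        fr = true_fr[label]
        scans[label] = {}
        for ex in config.excitation_list:
            amp = config.donor_amplitude * donor_excitation_scale(ex)
            direct = config.direct_at_max * refs.direct_profile(ex)
            scans[label][float(ex)] = simulate_spectrum(
                f_r=fr,
                donor_amplitude=amp,
                excitation_nm=ex,
                refs=refs,
                acceptor_direct_amount=direct,
                noise_sd=config.noise_sd,
                seed=rng,
                condition=label,
                construct_id=construct.construct_id,
            )
        # 515 nm excitation: donor essentially not excited, acceptor at its
        # direct-excitation maximum — the normalization scan.
        intensity = config.direct_at_max * refs.acceptor_emission
        if config.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, config.noise_sd, intensity.size)
        sample_direct[label] = Spectrum(
            wavelength_nm=refs.wavelength_nm.copy(),
            intensity=intensity,
            excitation_nm=refs.acceptor_peak_nm,
            condition=label,
            construct_id=construct.construct_id,
            ground_truth={"f_acc_direct": config.direct_at_max},
        )

    controls: dict[float, Spectrum] = {}
    control_amount = config.direct_at_max
    for ex in (*config.excitation_list, refs.acceptor_peak_nm):
        controls[float(ex)] = simulate_acceptor_only(
            ex, control_amount, refs, noise_sd=config.noise_sd, seed=rng
        )

    return EndpointDataset(
        construct=construct,
        protocol=ion_protocol,
        condition_order=labels,
        scans=scans,
        sample_direct_scans=sample_direct,
        control_scans=controls,
        references=refs,
        true_fr=true_fr,
        true_delta_fr=true_fr[labels[1]] - true_fr[labels[0]],
    )


_HILL_PARAM_SETS = {
    "force": {"p50", "n"},
    "single": {"f_min", "f_max", "n", "p50"},
    "double": {"f_min", "f_max1", "n1", "p50_1", "f_max2", "n2", "p50_2"},
}


def _hill_curve(model_params: dict, pX: np.ndarray) -> np.ndarray:
    params = dict(model_params)
    kind = params.pop("model", None)
    if kind is None:
        for k, names in _HILL_PARAM_SETS.items():
            if set(params) == names:
                kind = k
                break
    if kind not in _HILL_PARAM_SETS:
        raise ValueError(f"cannot identify Hill model from parameters {sorted(params)}")
    missing = _HILL_PARAM_SETS[kind] - set(params)
    if missing:
        raise ValueError(f"{kind} Hill model missing parameter(s) {sorted(missing)}")
    if kind == "force":
        return hill_force_model(pX, params["p50"], params["n"])
    if kind == "single":
        return single_hill_model(pX, params["f_min"], params["f_max"], params["n"], params["p50"])
    return double_hill_model(
        pX,
        params["f_min"],
        params["f_max1"], params["n1"], params["p50_1"],
        params["f_max2"], params["n2"], params["p50_2"],
    )


def _site_additive_curve(model_params: dict, pX: np.ndarray) -> np.ndarray:
    contrib: SiteContributions = model_params["contributions"]
    affinities: dict[str, float] = model_params["affinities"]
    f_min: float = model_params.get("f_min", 0.0)
    missing = set(contrib.contributions) - set(affinities)
    if missing:
        raise ValueError(f"no affinity supplied for site(s) {sorted(missing)}")
    resp = np.full_like(pX, f_min, dtype=float)
    for site, c in contrib.contributions.items():
        # single-site occupancy (n = 1) at each free-ion level
        resp += c / (1.0 + 10.0 ** (pX - affinities[site]))
    return resp


def simulate_titration(
    config: SimulationConfig,
    pX_grid: np.ndarray,
    replicates: int = 1,
    ion: str = "Ca",
    response_kind: str = "fret_ratio",
    construct_id: str = "",
) -> TitrationSeries:
    """Generate a replicate titration series from the configured model.

    ``config.mode == "hill"``: ``config.model_params`` holds the curve
    parameters (force, single or double Hill; see module docs).
    ``config.mode == "site-additive"``: ``model_params`` holds
    ``contributions`` (:class:`SiteContributions`), per-site ``affinities``
    (pX50 of single-site occupancy) and optional ``f_min``.
    Responses are the model curve plus i.i.d. Gaussian noise
    (``config.noise_sd``); ground truth is attached.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if config.model_params is None:
        raise ValueError("config.model_params is required")
    pX = np.asarray(pX_grid, dtype=float)
    if config.mode == "hill":
        curve = _hill_curve(config.model_params, pX)
    else:
        curve = _site_additive_curve(config.model_params, pX)

    rng = np.random.default_rng(config.seed)
    all_px, all_resp, all_rep = [], [], []
    for r in range(replicates):
        noise = rng.normal(0.0, config.noise_sd, pX.size) if config.noise_sd > 0 else 0.0
        all_px.append(pX)
        all_resp.append(curve + noise)
        all_rep.append(np.full(pX.size, r, dtype=int))
    return TitrationSeries(
        ion=ion,
        pX=np.concatenate(all_px),
        response=np.concatenate(all_resp),
        replicate=np.concatenate(all_rep),
        construct_id=construct_id,
        response_kind=response_kind,
        ground_truth={"mode": config.mode, **{k: v for k, v in config.model_params.items()}},
    )


def simulate_auc_distribution(
    peaks: list[GaussianPeak],
    s_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sedimentation-coefficient distribution: sum of Gaussian peaks + noise."""
    s = np.asarray(s_grid, dtype=float)
    freq = np.zeros_like(s)
    for p in peaks:
        if not s[0] <= p.s_mean <= s[-1]:
            raise ValueError(f"peak mean {p.s_mean} S outside s-grid [{s[0]}, {s[-1]}] S")
        freq += gaussian_peak_model(s, p.a0, p.s_mean, p.delta)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        freq = freq + rng.normal(0.0, noise_sd, s.size)
    return s, freq
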