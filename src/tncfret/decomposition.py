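"""Per-EF-hand decomposition of divalent-cation-dependent FRET signals.

Cardiac TnC carries three functional EF hands: regulatory site II in the
N-domain (Ca2+-specific, low affinity) and structural sites III/IV in the
C-domain (bind Ca2+ or Mg2+ with high affinity).  A panel of
site-inactivation constructs (each EF hand knocked out by mutating its
first coordinating Asp to Ala) yields one end-point signal dF_R per
construct.  Under the assumption that each site contributes independently
and additively to the FRET ratio, the construct signals are linear in the
per-site contributions:

    dF_R(construct) = baseline + sum_{site active in construct} c_site

where the baseline is the signal of the triple-knockout construct (no
functional EF hands).  :func:`decompose` solves this linear system by
(weighted) least squares; :func:`predict` evaluates the forward model; and
:func:`compare_to_wt` quantifies how well the additive prediction matches
the directly measured wild-type signal — a check on the independence
assumption.

Mg2+ binds, at most, very weakly at site II, so the Mg2+ panel excludes
site II from the design: only c_III, c_IV and the baseline are estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConstructDesign",
    "KNOCKOUT_PANEL",
    "ConstructSignal",
    "ConstructSignalSet",
    "SiteContributions",
    "decompose",
    "predict",
    "compare_to_wt",
    "WTComparison",
]

SITES = ("II", "III", "IV")
_SITES_BY_ION = {"Ca": ("II", "III", "IV"), "Mg": ("III", "IV")}


@dataclass(frozen=True)
class ConstructDesign:
    """A sensor construct identified by which EF hands remain functional."""

    construct_id: str
    active_sites: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.active_sites) - set(SITES)
        if bad:
            raise ValueError(f"unknown EF-hand site(s) {sorted(bad)}; valid: {SITES}")
        object.__setattr__(self, "active_sites", frozenset(self.active_sites))


#: The five-construct knockout panel: wild-type sensor, single C-domain
#: knockouts (D104A = site III out, D140A = site IV out), the C-domain
#: double knockout, and the triple knockout used as baseline.
KNOCKOUT_PANEL: dict[str, ConstructDesign] = {
    "CTV-TnC WT": ConstructDesign("CTV-TnC WT", frozenset({"II", "III", "IV"})),
    "D104A": ConstructDesign("D104A", frozenset({"II", "IV"})),
    "D140A": ConstructDesign("D140A", frozenset({"II", "III"})),
    "D104-140A": ConstructDesign("D104-140A", frozenset({"II"})),
    "3XEF": ConstructDesign("3XEF", frozenset()),
}


@dataclass(frozen=True)
class ConstructSignal:
    construct: ConstructDesign
    ion: str
    delta_fr: float
    se: float | None = None


@dataclass
class ConstructSignalSet:
    """End-point signals (dF_R, optional SE) for a construct panel, one ion."""

    entries: list[ConstructSignal]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty signal set")
        ions = {e.ion for e in self.entries}
        if len(ions) != 1:
            raise ValueError(f"mixed ions in signal set: {sorted(ions)}")
        ids = [e.construct.construct_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate constructs in signal set")

    @property
    def ion(self) -> str:
        return self.entries[0].ion


@dataclass
class SiteContributions:
    """Baseline-subtracted per-site F_R contributions plus baseline.

    ``contributions`` maps site name to its F_R contribution; for Mg the
    site-II entry is undefined (absent).  ``baseline`` is the signal of the
    no-functional-site construct, reported separately and already removed
    from the per-site values.
    """

    ion: str
    contributions: dict[str, float]
    baseline: float = 0.0
    se: dict[str, float] | None = None
    baseline_se: float | None = None
    residual_norm: float | None = None

    def __post_init__(self) -> None:
        if self.ion not in _SITES_BY_ION:
            raise ValueError(f"ion must be one of {sorted(_SITES_BY_ION)}, got {self.ion!r}")
        allowed = set(_SITES_BY_ION[self.ion])
        bad = set(self.contributions) - allowed
        if bad:
            raise ValueError(f"site(s) {sorted(bad)} not defined for {self.ion}")

    @property
    def sites(self) -> tuple[str, ...]:
        return _SITES_BY_ION[self.ion]


def _design_matrix(signals: ConstructSignalSet) -> tuple[np.ndarray, list[str]]:
    sites = list(_SITES_BY_ION[signals.ion])
    rows = []
    for e in signals.entries:
        rows.append([1.0 if s in e.construct.active_sites else 0.0 for s in sites] + [1.0])
    return np.asarray(rows), sites + ["baseline"]


def decompose(signals: ConstructSignalSet) -> SiteContributions:
    """Estimate per-site contributions from a construct panel.

    Solves dF_R = X b by weighted least squares with weights 1/SE^2 when
    every entry carries a positive SE, otherwise ordinary least squares.
    When the panel is exactly determined the result is the exact solve.
    Parameter SEs are propagated from the input SEs via (X' W X)^-1.

    Raises ``ValueError`` naming the unidentifiable columns if the design
    is rank deficient (e.g. no construct distinguishes two sites).
    """
    x, colnames = _design_matrix(signals)
    y = np.array([e.delta_fr for e in signals.entries])
    ncol = x.shape[1]
    if x.shape[0] < ncol:
        raise ValueError(
            f"{x.shape[0]} constructs cannot identify {ncol} unknowns ({colnames})"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < ncol:
        # name the columns involved in the null space
        _, _, vt = np.linalg.svd(x)
        null = np.abs(vt[rank:]).max(axis=0)
        bad = [c for c, v in zip(colnames, null) if v > 1e-8]
        raise ValueError(f"rank-deficient design: unidentifiable columns {bad}")

    ses = [e.se for e in signals.entries]
    weighted = all(s is not None and s > 0 for s in ses)
    w = 1.0 / np.array(ses, dtype=float) ** 2 if weighted else np.ones(len(y))
    xtwx = x.T @ (w[:, None] * x)
    beta = np.linalg.solve(xtwx, x.T @ (w * y))
    resid = y - x @ beta
    residual_norm = float(np.sqrt(np.sum(w * resid**2)))

    se_map = baseline_se = None
    if weighted:
        cov = np.linalg.inv(xtwx)
        errs = np.sqrt(np.diag(cov))
        se_map = {c: float(s) for c, s in zip(colnames[:-1], errs[:-1])}
        baseline_se = float(errs[-1])

    return SiteContributions(
        ion=signals.ion,
        contributions={c: float(b) for c, b in zip(colnames[:-1], beta[:-1])},
        baseline=float(beta[-1]),
        se=se_map,
        baseline_se=baseline_se,
        residual_norm=residual_norm,
    )


def predict(
    contributions: SiteContributions,
    construct: ConstructDesign,
    include_baseline: bool = False,
) -> float:
    """Forward-predict a construct's dF_R from per-site contributions.

    Sums the contributions of the construct's active sites that are defined
    for the ion (Mg predictions ignore site II).  With
    ``include_baseline=True`` the raw (non-baseline-subtracted) signal is
    returned; the default is the pure additive sum.
    """
    total = sum(
        contributions.contributions.get(s, 0.0)
        for s in construct.active_sites
        if s in contributions.sites
    )
    if include_baseline:
        total += contributions.baseline
    return float(total)


@dataclass(frozen=True)
class WTComparison:
    predicted: float
    observed: float
    discrepancy: float
    relative: float
    additivity_violation: bool | None


def compare_to_wt(
    predicted: float,
    observed_wt: float,
    predicted_se: float = 0.0,
    observed_se: float = 0.0,
) -> WTComparison:
    """Compare the additive prediction with the directly measured WT signal.

    The additivity-violation flag is set when the absolute discrepancy
    exceeds 3x the combined SE; it is ``None`` (not assessable) when no
    uncertainty is supplied.
    """
    d = observed_wt - predicted
    combined = float(np.hypot(predicted_se, observed_se))
    violation: bool | None
    violation = abs(d) > 3.0 * combined if combined > 0 else None
    rel = d / observed_wt if observed_wt != 0 else np.inf if d else 0.0
    return WTComparison(
        predicted=float(predicted),
        observed=float(observed_wt),
        discrepancy=float(d),
        relative=float(rel),
        additivity_violation=violation,
    )


#: Shipped default per-site contributions for the CTV-TnC sensor family
#: (representative characterization values; user-overridable).
DEFAULT_CA_CONTRIBUTIONS = SiteContributions(
    ion="Ca",
    contributions={"II": -0.120, "III": 0.224, "IV": 0.100},
    baseline=0.010,
)
DEFAULT_MG_CONTRIBUTIONS = SiteContributions(
    ion="Mg",
    contributions={"III": 0.079, "IV": 0.114},
    baseline=0.094,
)
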