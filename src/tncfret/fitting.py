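"""Titration-response and sedimentation-peak model fitting.

The response models, all written in pX = -log10 of free ion concentration:

force-pCa Hill (normalized force, numerator fixed at 100%):

    F(pCa) = 100 / (1 + 10^(n_H (pCa - pCa50)))

single Hill (e.g. Mg2+ titration of the FRET ratio):

    f(pX) = F_min + F_max / (1 + 10^(n (pX - pX50)))

double Hill (biphasic Ca2+ titration: high-affinity C-domain sites raise
F_R, the low-affinity N-domain site lowers it, so the second amplitude may
be negative):

    f(pCa) = F_min + F_max1 / (1 + 10^(n1 (pCa - pCa50_1)))
                   + F_max2 / (1 + 10^(n2 (pCa - pCa50_2)))

sedimentation-coefficient peak (3-parameter Gaussian over s in Svedberg):

    f(s) = A0 exp(-0.5 ((s - s_mean) / delta)^2)

Midpoints convert to association constants as K_a = 10^pX50 (L/mol);
reported K_a values follow the 2-significant-figure convention.

All fits are nonlinear least squares via lmfit with documented
initialization: offsets/amplitudes from the response extrema, Hill
coefficients started at 1 and bounded to [0.2, 6], and midpoints
multi-started on quantiles {0.25, 0.5, 0.75} of the observed pX range (all
ordered combinations for the double Hill).  Double-Hill components are
relabeled after convergence so component 1 is the higher-affinity
(larger-pX50) one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "TitrationSeries",
    "HillFit",
    "DoubleHillFit",
    "GaussianPeak",
    "hill_force_model",
    "single_hill_model",
    "double_hill_model",
    "gaussian_peak_model",
    "fit_hill_force",
    "fit_single_hill",
    "fit_double_hill",
    "fit_gaussian_peak",
    "ka_from_p50",
    "round_sig",
    "force_recovery",
    "ForceRecovery",
]

HILL_N_BOUNDS = (0.2, 6.0)
_P50_QUANTILES = (0.25, 0.5, 0.75)


# ---------------------------------------------------------------- containers
@dataclass
class TitrationSeries:
    """Replicate (pX, response) observations for one ion and construct."""

    ion: str
    pX: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    construct_id: str = ""
    response_kind: str = "fret_ratio"  # or "normalized_force"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.pX = np.asarray(self.pX, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.pX.shape != self.response.shape:
            raise ValueError("pX and response must have the same shape")
        if not np.all(np.isfinite(self.pX)):
            raise ValueError("non-finite pX values")
        if self.replicate is None:
            self.replicate = np.zeros(self.pX.size, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)

    @property
    def n_distinct(self) -> int:
        return np.unique(self.pX).size

    def noise_estimate(self) -> float:
        """Pooled replicate SD across pX points (0 with single replicates)."""
        variances = []
        for p in np.unique(self.pX):
            r = self.response[self.pX == p]
            if r.size >= 2:
                variances.append(np.var(r, ddof=1))
        return float(np.sqrt(np.mean(variances))) if variances else 0.0


@dataclass
class HillFit:
    p50: float
    n_h: float
    f_min: float
    f_max: float
    se: dict[str, float]
    converged: bool
    residual_ss: float
    flags: list[str] = field(default_factory=list)


@dataclass
class DoubleHillFit:
    f_min: float
    f_max1: float
    n1: float
    p50_1: float
    f_max2: float
    n2: float
    p50_2: float
    se: dict[str, float]
    converged: bool
    residual_ss: float
    covar: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class GaussianPeak:
    """One sedimentation peak: amplitude, mean s (Svedberg), SD of s."""

    a0: float
    s_mean: float
    delta: float
    se: dict[str, float] | None = None
    residual_ss: float | None = None

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("peak amplitude must be > 0")
        if self.delta <= 0:
            raise ValueError("peak SD delta must be > 0")


# ---------------------------------------------------------------- models
def hill_force_model(pCa, pca50, n_h):
    return 100.0 / (1.0 + 10.0 ** (n_h * (pCa - pca50)))


def single_hill_model(pX, f_min, f_max, n, p50):
    return f_min + f_max / (1.0 + 10.0 ** (n * (pX - p50)))


def double_hill_model(pCa, f_min, f_max1, n1, p50_1, f_max2, n2, p50_2):
    return (
        f_min
        + f_max1 / (1.0 + 10.0 ** (n1 * (pCa - p50_1)))
        + f_max2 / (1.0 + 10.0 ** (n2 * (pCa - p50_2)))
    )


def gaussian_peak_model(x, a0, s_mean, delta):
    return a0 * np.exp(-0.5 * ((x - s_mean) / delta) ** 2)


def _se_dict(result: lmfit.model.ModelResult) -> dict[str, float]:
    return {
        name: (float(p.stderr) if p.stderr is not None else float("nan"))
        for name, p in result.params.items()
    }


def _p50_starts(pX: np.ndarray) -> list[float]:
    lo, hi = float(pX.min()), float(pX.max())
    return [lo + q * (hi - lo) for q in _P50_QUANTILES]


# ---------------------------------------------------------------- fitters
def fit_hill_force(series: TitrationSeries) -> HillFit:
    """Fit the force–pCa Hill relation with the numerator fixed at 100%.

    Requires ``response_kind == "normalized_force"`` with responses in
    [-5, 110] %.  Data that *increase* with pCa (force rising as Ca2+
    falls) cannot be described by the model and are rejected.
    """
    if series.response_kind != "normalized_force":
        raise ValueError("fit_hill_force expects normalized_force data")
    y = series.response
    # sanity bound for normalized (%) data, widened by the measurement
    # noise so legitimate scatter around 0% / 100% is not rejected
    slack = 3.0 * series.noise_estimate()
    if y.min() < -5.0 - slack or y.max() > 110.0 + slack:
        raise ValueError("normalized force outside [-5, 110] %: data not normalized?")
    if series.n_distinct < 6:
        raise ValueError("need >= 6 distinct pCa points")
    slope = np.polyfit(series.pX, y, 1)[0]
    if slope > 0:
        raise ValueError("force increases with pCa: not a Ca-activated relation")

    model = lmfit.Model(hill_force_model, independent_vars=["pCa"])
    best = None
    for p50 in _p50_starts(series.pX):
        params = model.make_params(
            pca50=p50, n_h=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1])
        )
        res = model.fit(y, params, pCa=series.pX)
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise RuntimeError("force Hill fit failed to converge from all start points")
    return HillFit(
        p50=float(best.params["pca50"].value),
        n_h=float(best.params["n_h"].value),
        f_min=0.0,
        f_max=100.0,
        se=_se_dict(best),
        converged=bool(best.success),
        residual_ss=float(best.chisqr),
    )


def fit_single_hill(series: TitrationSeries) -> HillFit:
    """4-parameter single-Hill fit (offset, amplitude, n, midpoint)."""
    if series.n_distinct < 6:
        raise ValueError("need >= 6 distinct pX points for a single-Hill fit")
    y = series.response
    # flat-data check on replicate-averaged responses: averaging over R
    # replicates shrinks the noise floor by sqrt(R)
    px_values = np.unique(series.pX)
    means = np.array([np.mean(y[series.pX == p]) for p in px_values])
    reps = y.size / px_values.size
    span = float(means.max() - means.min())
    noise = series.noise_estimate() / np.sqrt(reps)
    if span == 0 or (noise > 0 and span < 5.0 * noise):
        raise ValueError("no transition: response range below 5x noise estimate")

    # f -> f_min at high pX (no ion); amplitude from the low-pX extreme
    hi_side = float(np.mean(y[series.pX == series.pX.max()]))
    lo_side = float(np.mean(y[series.pX == series.pX.min()]))
    model = lmfit.Model(single_hill_model, independent_vars=["pX"])
    best = None
    for p50 in _p50_starts(series.pX):
        params = model.make_params(
            f_min=hi_side,
            f_max=lo_side - hi_side if lo_side != hi_side else span,
            n=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1]),
            p50=p50,
        )
        res = model.fit(y, params, pX=series.pX)
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise RuntimeError("single Hill fit failed to converge from all start points")
    return HillFit(
        p50=float(best.params["p50"].value),
        n_h=float(best.params["n"].value),
        f_min=float(best.params["f_min"].value),
        f_max=float(best.params["f_max"].value),
        se=_se_dict(best),
        converged=bool(best.success),
        residual_ss=float(best.chisqr),
    )


def fit_double_hill(series: TitrationSeries) -> DoubleHillFit:
    """7-parameter biphasic double-Hill fit with multi-start midpoints.

    Components are relabeled after convergence so that component 1 has the
    larger pX50 (higher affinity); ties are broken by amplitude magnitude.
    A ``weakly_separated`` flag is set when |p50_1 - p50_2| < 0.3 pX units,
    and ``component{1,2}_weak`` when an amplitude is within 2 SE of zero.
    """
    if series.n_distinct < 10:
        raise ValueError("need >= 10 distinct pX points for a double-Hill fit")
    y = series.response
    hi_side = float(np.mean(y[series.pX == series.pX.max()]))
    lo_side = float(np.mean(y[series.pX == series.pX.min()]))
    rise = float(y.max()) - hi_side

    model = lmfit.Model(double_hill_model, independent_vars=["pCa"])
    starts = _p50_starts(series.pX)
    best = None
    for pa, pb in itertools.product(starts, starts):
        if pa == pb:
            continue
        params = model.make_params(
            f_min=hi_side,
            f_max1=rise if rise != 0 else 0.1,
            n1=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1]),
            p50_1=max(pa, pb),
            f_max2=lo_side - hi_side - rise,
            n2=dict(value=1.0, min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1]),
            p50_2=min(pa, pb),
        )
        try:
            res = model.fit(y, params, pCa=series.pX)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("double Hill fit failed to converge from all start points")

    p = best.params
    se = _se_dict(best)
    comp = [
        dict(f_max=p["f_max1"].value, n=p["n1"].value, p50=p["p50_1"].value,
             se_f=se["f_max1"], se_n=se["n1"], se_p=se["p50_1"]),
        dict(f_max=p["f_max2"].value, n=p["n2"].value, p50=p["p50_2"].value,
             se_f=se["f_max2"], se_n=se["n2"], se_p=se["p50_2"]),
    ]
    if comp[0]["p50"] < comp[1]["p50"] or (
        comp[0]["p50"] == comp[1]["p50"]
        and abs(comp[0]["f_max"]) < abs(comp[1]["f_max"])
    ):
        comp.reverse()

    flags = []
    if abs(comp[0]["p50"] - comp[1]["p50"]) < 0.3:
        flags.append("weakly_separated")
        warnings.warn("double-Hill midpoints closer than 0.3 pX units: weakly identified")
    for i, c in enumerate(comp, start=1):
        if np.isfinite(c["se_f"]) and c["se_f"] > 0 and abs(c["f_max"]) < 2 * c["se_f"]:
            flags.append(f"component{i}_weak")

    return DoubleHillFit(
        f_min=float(p["f_min"].value),
        f_max1=float(comp[0]["f_max"]),
        n1=float(comp[0]["n"]),
        p50_1=float(comp[0]["p50"]),
        f_max2=float(comp[1]["f_max"]),
        n2=float(comp[1]["n"]),
        p50_2=float(comp[1]["p50"]),
        se={
            "f_min": se["f_min"],
            "f_max1": comp[0]["se_f"], "n1": comp[0]["se_n"], "p50_1": comp[0]["se_p"],
            "f_max2": comp[1]["se_f"], "n2": comp[1]["se_n"], "p50_2": comp[1]["se_p"],
        },
        converged=True,
        residual_ss=float(best.chisqr),
        covar=best.covar,
        flags=flags,
    )


def fit_gaussian_peak(
    s_grid: np.ndarray,
    frequency: np.ndarray,
    window: tuple[float, float] | None = None,
    start_mean: float | None = None,
) -> GaussianPeak:
    """Fit one 3-parameter Gaussian to an s-distribution peak.

    ``window`` restricts the fit to an s-range isolating one peak; the
    window must contain a local maximum in its interior.  ``start_mean``
    overrides the default start (the windowed argmax).
    """
    s = np.asarray(s_grid, dtype=float)
    f = np.asarray(frequency, dtype=float)
    if window is not None:
        mask = (s >= window[0]) & (s <= window[1])
        s, f = s[mask], f[mask]
    if s.size < 4:
        raise ValueError("too few points in fitting window")
    imax = int(np.argmax(f))
    if imax in (0, s.size - 1) or f[imax] <= 0:
        raise ValueError("no interior local maximum in window")

    model = lmfit.Model(gaussian_peak_model, independent_vars=["x"])
    params = model.make_params(
        a0=dict(value=float(f[imax]), min=1e-12),
        s_mean=float(s[imax]) if start_mean is None else float(start_mean),
        delta=dict(value=max((s[-1] - s[0]) / 6.0, 1e-3), min=1e-6),
    )
    res = model.fit(f, params, x=s)
    if not res.success:
        raise RuntimeError("Gaussian peak fit failed to converge")
    return GaussianPeak(
        a0=float(res.params["a0"].value),
        s_mean=float(res.params["s_mean"].value),
        delta=float(res.params["delta"].value),
        se=_se_dict(res),
        residual_ss=float(res.chisqr),
    )


# ---------------------------------------------------------------- conversions
def ka_from_p50(p50: float) -> float:
    """Association constant K_a = 10^pX50 in L/mol (full precision).

    Use :func:`round_sig` for the conventional 2-significant-figure report.
    """
    if not np.isfinite(p50):
        raise ValueError("p50 must be finite")
    return float(10.0**p50)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


# ---------------------------------------------------------------- fiber QC
@dataclass(frozen=True)
class ForceRecovery:
    extraction_residual_pct: float
    recovery_pct: float
    extraction_ok: bool
    recovery_ok: bool


def force_recovery(
    force_pre: float,
    force_post_extraction: float,
    force_post_reconstitution: float,
) -> ForceRecovery:
    """Skinned-fiber QC: residual force after TnC extraction and recovery
    after reconstitution, both as % of the pre-extraction force P0.

    A preparation passes when the residual is strictly below 20% and the
    recovery strictly above 60%.
    """
    if force_pre <= 0:
        raise ValueError("pre-extraction force P0 must be > 0")
    residual = 100.0 * force_post_extraction / force_pre
    recovery = 100.0 * force_post_reconstitution / force_pre
    return ForceRecovery(
        extraction_residual_pct=residual,
        recovery_pct=recovery,
        extraction_ok=residual < 20.0,
        recovery_ok=recovery > 60.0,
    )
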