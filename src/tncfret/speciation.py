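"""Metal–chelator speciation in multi-ligand buffers.

Titration and fiber solutions buffer free Ca2+ and Mg2+ with chelators
(EGTA, EDTA, NTA, ATP...).  With apparent (pH-conditional) 1:1 association
constants K'(M, L), the simultaneous equilibria are

    [ML] = K'(M, L) [M]free [L]free         for every metal/ligand pair,

subject to mass balance for every species:

    M_total = [M]free + sum_L [ML]
    L_total = [L]free + sum_M [ML].

:func:`solve_free` solves this coupled system (forward problem);
:func:`total_for_free` inverts it, returning the total metal required to
reach a target free concentration — the quantity a solution recipe needs
(e.g. ~4.4 mM total Mg to hold 2 mM free Mg2+ in 2 mM EGTA + 5 mM NTA at
pH 7.0).  pX = -log10 of the free concentration links speciation to the
titration axis (pCa, pMg).

Constants are apparent at a stated pH; no proton chemistry, ionic-strength
or temperature corrections are computed.  Shipped defaults are
representative values for pH 7.0 and are user-overridable; a provenance
label travels with every constants table.

Solver: damped fixed-point iteration on the free concentrations (start at
free = total) followed by a Newton polish on log-concentrations; mass
balance is verified to 1e-10 relative on every solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "BufferSystem",
    "SpeciationResult",
    "ConvergenceError",
    "DEFAULT_CONSTANTS",
    "DEFAULT_CONSTANTS_PROVENANCE",
    "solve_free",
    "total_for_free",
    "pX",
]

MASS_BALANCE_TOL = 1e-10

#: Representative apparent 1:1 association constants, L/mol, pH 7.0
#: (user-overridable; supply your own table for quantitative recipes).
DEFAULT_CONSTANTS: dict[tuple[str, str], float] = {
    ("Ca", "EGTA"): 4.0e6,
    ("Mg", "EGTA"): 4.0e1,
    ("Ca", "EDTA"): 2.5e7,
    ("Mg", "EDTA"): 2.5e5,
    ("Ca", "NTA"): 5.0e3,
    ("Mg", "NTA"): 5.0e2,
    ("Ca", "ATP"): 5.0e3,
    ("Mg", "ATP"): 1.0e4,
}
DEFAULT_CONSTANTS_PROVENANCE = "shipped-default (representative, pH 7.0, user-overridable)"


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BufferSystem:
    """Totals and apparent constants for one buffer at fixed pH.

    ``metals``/``ligands`` map species name to total concentration (mol/L);
    ``constants`` maps (metal, ligand) to the apparent association constant
    K' (L/mol) — pairs absent from the table are treated as non-binding
    (K' = 0).  ``constants_provenance`` records where the table came from.
    """

    metals: dict[str, float]
    ligands: dict[str, float]
    constants: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS)
    )
    pH: float = 7.0
    temperature_c: float = 22.0
    constants_provenance: str = DEFAULT_CONSTANTS_PROVENANCE

    def __post_init__(self) -> None:
        for name, tot in {**self.metals, **self.ligands}.items():
            if tot < 0:
                raise ValueError(f"negative total for {name!r}")
        for pair, k in self.constants.items():
            if k <= 0:
                raise ValueError(f"association constant for {pair} must be > 0")

    def k(self, metal: str, ligand: str) -> float:
        return self.constants.get((metal, ligand), 0.0)

    def with_total(self, metal: str, total: float) -> "BufferSystem":
        metals = dict(self.metals)
        metals[metal] = total
        return BufferSystem(
            metals=metals,
            ligands=dict(self.ligands),
            constants=self.constants,
            pH=self.pH,
            temperature_c=self.temperature_c,
            constants_provenance=self.constants_provenance,
        )


@dataclass
class SpeciationResult:
    free: dict[str, float]
    free_ligand: dict[str, float]
    complexes: dict[tuple[str, str], float]
    max_mass_balance_residual: float
    converged: bool

    def pX(self, metal: str) -> float:
        return pX(self.free[metal])


def _mass_balance_residual(
    system: BufferSystem,
    free_m: dict[str, float],
    free_l: dict[str, float],
) -> float:
    worst = 0.0
    for m, tot in system.metals.items():
        if tot == 0:
            continue
        bound = sum(system.k(m, l) * free_m[m] * free_l[l] for l in system.ligands)
        worst = max(worst, abs(free_m[m] + bound - tot) / tot)
    for l, tot in system.ligands.items():
        if tot == 0:
            continue
        bound = sum(system.k(m, l) * free_m[m] * free_l[l] for m in system.metals)
        worst = max(worst, abs(free_l[l] + bound - tot) / tot)
    return worst


def solve_free(system: BufferSystem, max_iter: int = 500) -> SpeciationResult:
    """Solve the coupled 1:1 equilibria for free and bound concentrations.

    Raises :class:`ConvergenceError` with the residual if the mass-balance
    tolerance (1e-10 relative) cannot be met.
    """
    metals = [m for m, t in system.metals.items() if t > 0]
    ligands = [l for l, t in system.ligands.items() if t > 0]
    zero_metals = {m: 0.0 for m, t in system.metals.items() if t == 0}
    zero_ligands = {l: 0.0 for l, t in system.ligands.items() if t == 0}

    if not metals or not ligands:
        free_m = {m: system.metals[m] for m in metals} | zero_metals
        free_l = {l: system.ligands[l] for l in ligands} | zero_ligands
        complexes = {
            (m, l): 0.0 for m in system.metals for l in system.ligands
        }
        return SpeciationResult(free_m, free_l, complexes, 0.0, True)

    mt = np.array([system.metals[m] for m in metals])
    lt = np.array([system.ligands[l] for l in ligands])
    kmat = np.array([[system.k(m, l) for l in ligands] for m in metals])

    # Given the free metals, each ligand's mass balance solves in closed
    # form: [L]free = L_tot / (1 + sum_M K [M]free).  This eliminates the
    # ligand unknowns and leaves a small metals-only system.
    def free_ligands(fm: np.ndarray) -> np.ndarray:
        return lt / (1.0 + kmat.T @ fm)

    def metal_residual(fm: np.ndarray) -> np.ndarray:
        return (fm * (1.0 + kmat @ free_ligands(fm)) - mt) / mt

    # damped fixed point, deterministic start at free = total
    fm = mt.copy()
    for _ in range(max_iter):
        fm = 0.5 * fm + 0.5 * mt / (1.0 + kmat @ free_ligands(fm))

    sol = optimize.root(
        lambda logx: metal_residual(np.exp(logx)), np.log(fm), method="hybr", tol=1e-14
    )
    fm = np.exp(sol.x)

    if np.max(np.abs(metal_residual(fm))) > MASS_BALANCE_TOL:
        # stiff near-equivalence systems: Gauss-Seidel sweeps of bracketed
        # 1-D solves — each metal's balance is monotone in its own free
        # concentration with the others held fixed
        fm = np.minimum(fm, mt)
        for _ in range(200):
            for i in range(len(metals)):
                def one(logx, i=i):
                    trial = fm.copy()
                    trial[i] = np.exp(logx)
                    return metal_residual(trial)[i]

                lo = np.log(mt[i]) - 60.0
                hi = np.log(mt[i])
                if one(hi) < 0:
                    fm[i] = mt[i]
                    continue
                fm[i] = np.exp(optimize.brentq(one, lo, hi, xtol=1e-15, rtol=8.9e-16))
            if np.max(np.abs(metal_residual(fm))) < MASS_BALANCE_TOL:
                break

    fl = free_ligands(fm)
    free_m = {m: float(v) for m, v in zip(metals, fm)} | zero_metals
    free_l = {l: float(v) for l, v in zip(ligands, fl)} | zero_ligands

    worst = _mass_balance_residual(system, free_m, free_l)
    if worst > MASS_BALANCE_TOL:
        raise ConvergenceError(
            f"speciation did not converge: max relative mass-balance residual "
            f"{worst:.3e} > {MASS_BALANCE_TOL:.0e}"
        )
    complexes = {
        (m, l): system.k(m, l) * free_m[m] * free_l[l]
        for m in system.metals
        for l in system.ligands
    }
    return SpeciationResult(free_m, free_l, complexes, worst, True)


def total_for_free(system: BufferSystem, metal: str, target_free: float) -> float:
    """Total metal needed to reach ``target_free`` (inverse problem).

    The forward map total -> free is strictly increasing, so the root is
    bracketed between the target itself (no binding) and the target plus
    everything the ligands could possibly bind, and found by Brent's
    method; the round trip through :func:`solve_free` reproduces the
    target to better than 1e-9 relative.
    """
    if target_free <= 0:
        raise ValueError("target free concentration must be > 0")
    if metal not in system.metals:
        raise ValueError(f"unknown metal {metal!r}")
    ligand_capacity = sum(system.ligands.values())
    if ligand_capacity == 0:
        return target_free

    def gap(total: float) -> float:
        return solve_free(system.with_total(metal, total)).free[metal] - target_free

    lo = target_free
    hi = target_free + ligand_capacity
    if gap(lo) >= 0:
        return lo
    total = optimize.brentq(gap, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200)
    return float(total)


def pX(free: float) -> float:
    """pX = -log10 of a free concentration in mol/L (pCa, pMg)."""
    if free <= 0:
        raise ValueError("free concentration must be > 0")
    return float(-np.log10(free))
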