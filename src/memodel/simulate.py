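"""Flux balance analysis on ME models: LP solves, numerical verification,
reduced-cost bottleneck reports, knockouts and screens.

The LP is  max v_obj  s.t.  S v = 0,  A v <= 0 (coupling rows),  lb <= v <= ub,
solved with HiGHS via scipy.  Multiscale models are ill-scaled (coefficients
span many orders of magnitude); if the solver fails, a geometric-mean column
scaling is applied and the solve retried, and every reported solution can be
re-checked against the constraints with `verify_solution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model import BiomassAdjustment, MEModel, adjust_biomass, apply_media

__all__ = [
    "FBASolution",
    "VerificationReport",
    "EssentialityRecord",
    "solve_fba",
    "verify_solution",
    "reduced_cost_report",
    "knockout_gene",
    "deletion_screen",
    "growth_screen",
    "biomass_sensitivity_scan",
]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FBASolution:
    status: str
    objective_value: float
    fluxes: pd.Series
    reduced_costs: pd.Series
    species_duals: pd.Series
    coupling_duals: pd.Series
    objective_id: str
    scaled: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _geometric_column_scaling(A: sparse.csr_matrix) -> np.ndarray:
    """Per-column factor 1/sqrt(max|a| * min|a|) over nonzeros."""
    A = A.tocsc()
    d = np.ones(A.shape[1])
    for j in range(A.shape[1]):
        col = np.abs(A.data[A.indptr[j] : A.indptr[j + 1]])
        col = col[col > 0]
        if col.size:
            d[j] = 1.0 / math.sqrt(float(col.max()) * float(col.min()))
    return d


def solve_fba(model: MEModel, objective: str | None = None) -> FBASolution:
    """Maximize an objective flux subject to mass balance, bounds and couplings."""
    obj = objective or model.objective_id
    if not obj or obj not in model.reactions:
        raise ValueError(f"objective reaction {obj!r} not in model")

    S, species_ids, rxn_ids = model.stoichiometric_matrix()
    A_c, labels = model.coupling_matrix()
    lb, ub = model.bounds()
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(obj)] = -1.0

    def _run(scale: np.ndarray | None):
        if scale is None:
            Se, Ae, lbe, ube, ce = S, A_c, lb, ub, c
        else:
            D = sparse.diags(scale)
            Se, Ae = S @ D, A_c @ D
            lbe, ube, ce = lb / scale, ub / scale, c * scale
        kw = {}
        if Ae.shape[0]:
            kw = {"A_ub": Ae, "b_ub": np.zeros(Ae.shape[0])}
        return linprog(
            ce, A_eq=Se, b_eq=np.zeros(S.shape[0]),
            bounds=np.column_stack([lbe, ube]), method="highs", **kw,
        )

    res = _run(None)
    scaled = False
    if res.status in (1, 4):
        stacked = sparse.vstack([S, A_c]) if A_c.shape[0] else S
        d = _geometric_column_scaling(stacked)
        res_s = _run(d)
        if res_s.status == 0:
            res, scaled = res_s, True
            res.x = res.x * d
            res.lower.marginals = res.lower.marginals / d
            res.upper.marginals = res.upper.marginals / d
        else:
            raise RuntimeError(
                f"solver failed after rescaling retry (status {res.status} then "
                f"{res_s.status}); column scale span "
                f"{d.min():.2e}..{d.max():.2e}"
            )

    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        empty = pd.Series(dtype=float)
        return FBASolution(status, math.nan, empty, empty, empty, empty, obj, scaled)

    fluxes = pd.Series(res.x, index=rxn_ids)
    # reduced cost = d(objective)/d(bound); positive entries belong to upper
    # bounds whose relaxation raises growth, negative to lower bounds whose
    # relaxation (decrease) raises it.
    rc = -(res.lower.marginals + res.upper.marginals)
    reduced_costs = pd.Series(rc, index=rxn_ids)
    species_duals = pd.Series(-res.eqlin.marginals, index=species_ids)
    coupling_duals = pd.Series(
        -res.ineqlin.marginals if A_c.shape[0] else [], index=labels, dtype=float
    )
    return FBASolution(
        "optimal", float(-res.fun), fluxes, reduced_costs, species_duals,
        coupling_duals, obj, scaled,
    )


@dataclass
class VerificationReport:
    mass_balance_residual: float
    bound_violation: float
    coupling_violation: float
    tol: float
    checks: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def verify_solution(model: MEModel, solution: FBASolution, tol: float = 1e-6) -> VerificationReport:
    """Check a flux vector lies in the solution space: |S v| <= tol,
    lb - tol <= v <= ub + tol, and coupling rows A v <= tol."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    v = solution.fluxes.reindex(rxn_ids).to_numpy()
    lb, ub = model.bounds()
    mass = float(np.abs(S @ v).max()) if S.shape[0] else 0.0
    bound = float(np.maximum(lb - v, v - ub).max()) if len(v) else 0.0
    A_c, _ = model.coupling_matrix()
    coup = float((A_c @ v).max()) if A_c.shape[0] else 0.0
    checks = {
        "mass_balance": mass <= tol,
        "bounds": bound <= tol,
        "couplings": coup <= tol,
    }
    return VerificationReport(mass, max(bound, 0.0), max(coup, 0.0), tol, checks)


def reduced_cost_report(
    model: MEModel,
    solution: FBASolution,
    top_k: int = 10,
    threshold: float = 1e-9,
    include_irreversibility_bounds: bool = False,
) -> pd.DataFrame:
    """Bounded variables ranked by |reduced cost| (ties broken by reaction id).

    Only bounds that are active at optimality carry a nonzero reduced cost;
    with no binding bounds the report is empty.  Zero lower bounds encode
    irreversibility, whose "relaxation" (running a reaction backwards) is
    not a physically meaningful intervention, so they are excluded unless
    ``include_irreversibility_bounds`` is set.
    """
    if not solution.optimal:
        raise ValueError("reduced costs require an optimal solution")
    lb, ub = model.bounds()
    rows = []
    for j, rid in enumerate(model.reaction_ids):
        rc = solution.reduced_costs.iloc[j]
        if abs(rc) <= threshold:
            continue
        v = solution.fluxes.iloc[j]
        bound = "ub" if (np.isfinite(ub[j]) and abs(v - ub[j]) <= abs(v - lb[j])) else "lb"
        if bound == "lb" and lb[j] == 0 and not include_irreversibility_bounds:
            continue
        rows.append((rid, bound, float(rc)))
    rows.sort(key=lambda r: (-abs(r[2]), r[0]))
    return pd.DataFrame(rows[:top_k], columns=["reaction_id", "bound", "reduced_cost"])


# ---------------------------------------------------------------------------
# Knockouts and screens


def knockout_gene(model: MEModel, locus: str, mode: str = "local") -> MEModel:
    """In silico deletion of a protein-coding gene.

    Translation-initiation bounds for the locus are zeroed and the coupling
    constraints referencing the gene's synthesis/usage reactions are removed.
    In the default ``local`` mode the metabolic-unit reactions of enzymes
    that require the locus are additionally forced to zero, so the deletion
    semantics (no synthesis => no catalysis) survive coupling removal;
    isozyme-backed units stay open.  ``literal`` mode performs only the
    bound zeroing and coupling removal.
    """
    if locus not in model.gene_index:
        raise KeyError(f"unknown locus {locus!r}")
    info = model.gene_index[locus]
    if info["product_type"] != "protein":
        raise ValueError(f"{locus}: only protein-coding knockouts are defined")
    if mode not in ("local", "literal"):
        raise ValueError(f"unknown knockout mode {mode!r}")

    m = model.copy()
    tl = m.reactions[info["tl_ini"]]
    tl.lb = tl.ub = 0.0

    touched = set(info["expression_reactions"]) | set(info["unit_reactions"])
    m.couplings = [
        cc for cc in m.couplings if cc.v_syn not in touched and cc.v_use not in touched
    ]
    if mode == "local":
        for rid in info["unit_reactions"]:
            rxn = m.reactions[rid]
            rxn.lb = rxn.ub = 0.0
    return m


@dataclass(frozen=True)
class EssentialityRecord:
    locus_id: str
    growth: float
    wildtype_growth: float
    essential: bool
    status: str


def deletion_screen(
    model: MEModel,
    loci: list[str] | None = None,
    threshold: float = 0.05,
    mode: str = "local",
) -> pd.DataFrame:
    """Single-gene deletion growth phenotypes.

    A gene is flagged essential when knockout growth falls below
    ``threshold`` (default 5%) of the wildtype optimum; infeasible knockouts
    count as zero growth.  LP failures are recorded per gene, not fatal.
    """
    if loci is None:
        loci = sorted(
            l for l, i in model.gene_index.items() if i["product_type"] == "protein"
        )
    wt = solve_fba(model)
    if not wt.optimal:
        raise RuntimeError(f"wildtype model does not solve: {wt.status}")
    records = []
    for locus in loci:
        try:
            sol = solve_fba(knockout_gene(model, locus, mode=mode))
            growth = sol.objective_value if sol.optimal else 0.0
            status = sol.status
        except Exception as exc:  # noqa: BLE001 - per-cell failures recorded
            growth, status = math.nan, f"error: {exc}"
        records.append(
            EssentialityRecord(
                locus, growth, wt.objective_value,
                bool(growth < threshold * wt.objective_value) if not math.isnan(growth) else False,
                status,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


def growth_screen(model: MEModel, media_list: dict[str, dict]) -> pd.DataFrame:
    """Optimal growth per medium; infeasible media score zero growth."""
    if not media_list:
        raise ValueError("empty media list")
    rows = []
    for name, media in media_list.items():
        try:
            sol = solve_fba(apply_media(model.copy(), media))
            rows.append((name, sol.status, sol.objective_value if sol.optimal else 0.0))
        except Exception as exc:  # noqa: BLE001
            rows.append((name, f"error: {exc}", math.nan))
    return pd.DataFrame(rows, columns=["medium", "status", "growth"])


def biomass_sensitivity_scan(
    model: MEModel, aa_fracs: list[float], gam_fracs: list[float]
) -> pd.DataFrame:
    """Growth surface over amino-acid and GAM biomass fractions.

    Fractions apply to the model's current biomass reaction (pass the
    unadjusted model for an absolute surface).  Index: aa fraction, columns:
    GAM fraction.
    """
    if not aa_fracs or not gam_fracs:
        raise ValueError("empty fraction grid")
    surface = np.full((len(aa_fracs), len(gam_fracs)), np.nan)
    for i, fa in enumerate(aa_fracs):
        for j, fg in enumerate(gam_fracs):
            m = adjust_biomass(model.copy(), BiomassAdjustment(fa, fg))
            sol = solve_fba(m)
            surface[i, j] = sol.objective_value if sol.optimal else 0.0
    return pd.DataFrame(surface, index=pd.Index(aa_fracs, name="aa_fraction"),
                        columns=pd.Index(gam_fracs, name="gam_fraction"))
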