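"""Enzyme-explicit reformulation of metabolic reactions ("metabolic units").

Each GPR-associated metabolic reaction is replaced, per isozyme module and
per allowed direction, by an activation / catalytic / recycle cycle plus one
shared demand reaction on the enzyme:

    activation   ENZ -> ENZ_dir_active
    catalytic    substrates + ENZ_dir_active -> products + ENZ_dir_inactive
    recycle      ENZ_dir_inactive -> ENZ            (id suffix _DREC)
    demand       ENZ ->                              (id DM_<enzyme>)

Summing one activation + catalytic + recycle cycle nets exactly the original
metabolic conversion (the enzyme species cancel), so metabolite balance is
preserved.  An irreversible reaction yields a 4-reaction unit, a reversible
one a 7-reaction unit with direction-specific enzyme pools.  The demand flux
is the enzyme's dilution and is the synthesis-side anchor for the coupling
constraints; the recycle flux counts catalytic turnovers and is the
utilization side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .expression import (
    ComplexSpec,
    Reaction,
    build_complex_formation,
    build_enzyme_transport,
)
from .gpr import GPR, parse_gpr

__all__ = [
    "MetabolicUnit",
    "ExpansionResult",
    "expand_reaction",
    "expand_reactions",
    "parse_reaction_formula",
    "read_reaction_table",
    "strip_trna_charging",
    "ARTIFICIAL_GENE",
]

ARTIFICIAL_GENE = "s0001"


@dataclass(frozen=True)
class MetabolicUnit:
    """The reaction set replacing one metabolic reaction for one isozyme module."""

    source_id: str
    enzyme_id: str
    module: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    demand_id: str
    recycle_ids: tuple[str, ...]
    directionality: str  # "forward" or "both"

    def __post_init__(self) -> None:
        expected = 4 if self.directionality == "forward" else 7
        if len(self.reaction_ids) != expected:
            raise ValueError(
                f"{self.source_id}: {self.directionality} unit must have {expected} "
                f"reactions, got {len(self.reaction_ids)}"
            )


@dataclass
class ExpansionResult:
    units: list[MetabolicUnit] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    complex_specs: list[ComplexSpec] = field(default_factory=list)
    spontaneous: list[Reaction] = field(default_factory=list)


def _enzyme_species(module: tuple[str, ...], complexes: dict[tuple[str, ...], ComplexSpec]) -> tuple[str, ComplexSpec | None]:
    """Enzyme species for a module: the bare protein for a monomer, a complex otherwise."""
    if len(module) == 1:
        return f"protein_{module[0]}", None
    spec = complexes.get(module)
    if spec is None:
        spec = ComplexSpec(
            complex_id="_".join(module),
            subunits=tuple((locus, 1) for locus in module),
        )
    return f"cplx_{spec.complex_id}", spec


def expand_reaction(
    reaction: Reaction,
    gpr: GPR | str | None = None,
    compartment: str = "c",
    complexes: dict[tuple[str, ...], ComplexSpec] | None = None,
) -> ExpansionResult:
    """Reformulate one metabolic reaction into enzyme-explicit metabolic units.

    ``complexes`` optionally maps a sorted subunit-locus tuple to a curated
    ComplexSpec (stoichiometry, metallo-ions); AND modules without an entry
    get a default 1:1 complex.  Reactions without a GPR pass through
    unchanged (spontaneous).
    """
    if gpr is None and reaction.gpr:
        gpr = reaction.gpr
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr) if gpr.strip() else None
    if gpr is not None:
        gpr = gpr.without_gene(ARTIFICIAL_GENE)

    result = ExpansionResult()
    if gpr is None:
        result.spontaneous.append(reaction.copy())
        result.reactions.append(reaction.copy())
        return result

    complexes = complexes or {}
    seen_aux: set[str] = set()
    for idx, module in enumerate(gpr.modules, start=1):
        base = f"{reaction.id}{idx}"
        enz, cplx_spec = _enzyme_species(module, complexes)
        if cplx_spec is not None and enz not in seen_aux:
            result.reactions.append(build_complex_formation(cplx_spec))
            result.complex_specs.append(cplx_spec)
            seen_aux.add(enz)

        enz_local = enz if compartment == "c" else f"{enz}_{compartment}"
        if compartment != "c":
            for t in build_enzyme_transport(enz, compartment):
                if t.id not in seen_aux:
                    result.reactions.append(t)
                    seen_aux.add(t.id)

        unit_rxns: list[Reaction] = []
        recycle_ids: list[str] = []
        directions = [("", 1)] + ([("_REV", -1)] if reaction.reversible else [])
        for suffix, sign in directions:
            active = f"{enz_local}__{base}{suffix}_act"
            inactive = f"{enz_local}__{base}{suffix}_inact"
            act = Reaction(
                f"{base}{suffix}_ACT",
                {enz_local: -1.0, active: 1.0},
                subsystem="Metabolism",
            )
            cat_stoich = {s: sign * c for s, c in reaction.stoichiometry.items()}
            cat_stoich[active] = -1.0
            cat_stoich[inactive] = 1.0
            cat = Reaction(
                f"{base}{suffix}",
                cat_stoich,
                lb=0.0,
                ub=reaction.ub if suffix == "" else abs(reaction.lb) if reaction.lb < 0 else reaction.ub,
                subsystem="Metabolism",
            )
            rec = Reaction(
                f"{base}{suffix}_DREC",
                {inactive: -1.0, enz_local: 1.0},
                subsystem="Protein recycling",
            )
            unit_rxns.extend([act, cat, rec])
            recycle_ids.append(rec.id)

        demand = Reaction(
            f"DM_{enz_local}", {enz_local: -1.0}, subsystem="Demands & Sinks"
        )
        unit_rxns.append(demand)
        result.reactions.extend(unit_rxns)
        result.units.append(
            MetabolicUnit(
                source_id=reaction.id,
                enzyme_id=enz_local,
                module=module,
                reaction_ids=tuple(r.id for r in unit_rxns),
                demand_id=demand.id,
                recycle_ids=tuple(recycle_ids),
                directionality="both" if reaction.reversible else "forward",
            )
        )
    return result


def expand_reactions(
    reactions: list[Reaction],
    complexes: dict[tuple[str, ...], ComplexSpec] | None = None,
    compartments: dict[str, str] | None = None,
) -> ExpansionResult:
    """Expand a reaction list; exchange reactions and GPR-less reactions pass through."""
    compartments = compartments or {}
    merged = ExpansionResult()
    seen: set[str] = set()
    for rxn in reactions:
        if rxn.is_exchange or not rxn.gpr.strip():
            merged.spontaneous.append(rxn.copy())
            merged.reactions.append(rxn.copy())
            continue
        one = expand_reaction(rxn, compartment=compartments.get(rxn.id, "c"), complexes=complexes)
        merged.units.extend(one.units)
        merged.complex_specs.extend(one.complex_specs)
        merged.spontaneous.extend(one.spontaneous)
        for r in one.reactions:
            if r.id in seen:
                continue  # shared complex formation / transport across reactions
            seen.add(r.id)
            merged.reactions.append(r)
    return merged


# ---------------------------------------------------------------------------
# Reaction-table input

_ARROW = re.compile(r"<=>|<->|-->|->")
_TERM = re.compile(r"^\s*(?:(\d*\.?\d+(?:[eE][+-]?\d+)?)\s+)?([\w.\-]+)\[([cpe])\]\s*$")


def parse_reaction_formula(
    rxn_id: str,
    formula: str,
    gpr: str = "",
    subsystem: str = "Metabolism",
    lb: float | None = None,
    ub: float | None = None,
) -> Reaction:
    """Parse a formula string like ``a[c] + 2 b[c] -> c[p]`` (``<=>`` reversible)."""
    m = _ARROW.search(formula)
    if not m:
        raise ValueError(f"{rxn_id}: no reaction arrow in {formula!r}")
    reversible = m.group(0) in ("<=>", "<->")
    left, right = formula[: m.start()], formula[m.end() :]
    stoich: dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        for term in side.split("+"):
            if not term.strip():
                continue
            tm = _TERM.match(term)
            if not tm:
                raise ValueError(f"{rxn_id}: cannot parse term {term.strip()!r}")
            coeff = float(tm.group(1)) if tm.group(1) else 1.0
            sid = f"{tm.group(2)}_{tm.group(3)}"
            stoich[sid] = stoich.get(sid, 0.0) + sign * coeff

    _add(left, -1.0)
    _add(right, +1.0)
    default_lb = -1000.0 if reversible else 0.0
    return Reaction(
        rxn_id,
        stoich,
        reversible=reversible,
        lb=default_lb if lb is None else lb,
        ub=1000.0 if ub is None else ub,
        subsystem=subsystem,
        gpr=gpr,
    )


def read_reaction_table(path) -> list[Reaction]:
    """Read a TSV reaction table: id, formula, gpr (optional), subsystem (optional)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t").fillna("")
    if not {"id", "formula"} <= set(df.columns):
        raise ValueError("reaction table requires 'id' and 'formula' columns")
    out = []
    for _, row in df.iterrows():
        out.append(
            parse_reaction_formula(
                str(row["id"]),
                str(row["formula"]),
                gpr=str(row.get("gpr", "")),
                subsystem=str(row.get("subsystem", "Metabolism")) or "Metabolism",
            )
        )
    return out


def strip_trna_charging(reactions: list[Reaction]) -> list[Reaction]:
    """Drop tRNA-charging reactions from a metabolic input before integration.

    The expression side regenerates charging from the recognition map, so
    metabolic-side duplicates must be removed first.
    """
    return [
        r
        for r in reactions
        if r.subsystem != "tRNA charging" and not r.id.startswith("CHRG_")
    ]
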