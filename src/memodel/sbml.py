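"""SBML Level 3 export of ME models.

JSON (MEModel.to_json) is the primary serialization; SBML export is provided
for interoperability with constraint-based tooling.  Coupling constraints
have no SBML core representation and are written as model annotations.
"""

from __future__ import annotations

import math
from pathlib import Path

from .model import MEModel

_BOUND_CAP = 1e6  # stand-in for infinite bounds in SBML parameters


def export_sbml(model: MEModel, path: str | Path) -> None:
    """Write an SBML L3 document: species, reactions, bounds as parameters."""
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("SBML export requires python-libsbml") from exc

    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel("me_model")
    for comp_id in ("c", "p", "e"):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    def _sid(raw: str) -> str:
        out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
        return out if out[0].isalpha() or out[0] == "_" else f"x_{out}"

    for sp in model.species.values():
        s = sm.createSpecies()
        s.setId(_sid(sp.id))
        s.setCompartment(sp.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    def _finite(x: float) -> float:
        if math.isinf(x):
            return _BOUND_CAP if x > 0 else -_BOUND_CAP
        return x

    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(_sid(rxn.id))
        r.setReversible(rxn.reversible)
        for sid, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(_sid(sid))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        for suffix, value in (("lb", rxn.lb), ("ub", rxn.ub)):
            p = sm.createParameter()
            p.setId(_sid(f"{rxn.id}_{suffix}"))
            p.setValue(_finite(value))
            p.setConstant(True)

    notes = "; ".join(
        f"coupling {c.v_syn}->{c.v_use} [{c.c_min},{c.c_max}]" for c in model.couplings
    )
    if notes:
        sm.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>{notes}</p></body>")
    libsbml.writeSBMLToFile(doc, str(path))
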