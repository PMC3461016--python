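"""Assembly of the integrated metabolism-and-expression (ME) model.

The ME model is an ordinary stoichiometric model (S·v = 0, bounds, a biomass
objective) extended with linear *coupling constraints* that tie each
macromolecule's synthesis flux to its utilization flux.  A coupling with
coefficients (c_min, c_max) adds the inequality pair

    v_use - c_max * v_syn <= 0          (use requires synthesis)
    c_min * v_syn - v_use <= 0          (omitted when c_min = 0)

i.e. the ratio v_use / v_syn is confined to [c_min, c_max] whenever either
flux is nonzero.  Zero synthesis therefore forces zero utilization, and a
higher utilization flux raises the minimum feasible synthesis flux.  Both
rows are stored explicitly so alternative algebraic forms can be swapped
without touching callers.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .expression import INF, Reaction, Species, declare_species
from .units import MetabolicUnit

__all__ = [
    "CouplingConstraint",
    "TranslationCouplingParams",
    "BiomassAdjustment",
    "BiomassTags",
    "ModelPart",
    "MEModel",
    "assemble",
    "add_coupling",
    "mrna_coupling_coefficient",
    "adjust_biomass",
    "apply_media",
    "set_transcription_caps",
    "reconstruction_statistics",
    "load_reference_process_counts",
    "verify_process_counts",
    "base_medium",
    "load_media",
]


@dataclass(frozen=True)
class CouplingConstraint:
    """Proportionality band between a synthesis flux and a utilization flux."""

    v_syn: str
    v_use: str
    c_min: float
    c_max: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.c_min < 0 or self.c_max < 0:
            raise ValueError(f"coupling {self.v_syn}->{self.v_use}: negative coefficient")
        if self.c_min > self.c_max:
            raise ValueError(f"coupling {self.v_syn}->{self.v_use}: c_min > c_max")


@dataclass(frozen=True)
class TranslationCouplingParams:
    """Parameters of the mRNA-to-translation coupling coefficient.

    The number of translations one transcript supports before turnover is
    k_translation * t_half / L, with k_translation in aa/s, the half-life in
    minutes (bounded to [0.1, 60] min) and the protein length L in aa.
    """

    rate_aa_per_s: float = 12.0
    length_aa: int = 300
    t_half_min: float = 0.1
    t_half_max: float = 60.0

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError("protein length must be positive")
        if not (0.1 <= self.t_half_min <= self.t_half_max <= 60.0):
            raise ValueError("mRNA half-life bounds must satisfy 0.1 <= lo <= hi <= 60 min")


@dataclass(frozen=True)
class BiomassAdjustment:
    """Fractions of amino-acid content and GAM retained in the biomass reaction."""

    aa_fraction: float = 0.5
    gam_fraction: float = 0.5

    def __post_init__(self) -> None:
        for f in (self.aa_fraction, self.gam_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("biomass fractions must lie in [0, 1]")


@dataclass
class BiomassTags:
    """Bookkeeping for adjustable biomass terms.

    ``gam_species`` gives the per-unit-GAM signed stoichiometry of the ATP
    hydrolysis terms (atp/h2o negative, adp/pi/h positive); ``gam`` is the
    current GAM magnitude so adjustments compose multiplicatively.
    """

    aa_species: tuple[str, ...]
    gam: float
    gam_species: dict[str, float] = field(
        default_factory=lambda: {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}
    )


@dataclass
class ModelPart:
    """One reconstruction to merge: a named reaction list with its species."""

    name: str
    reactions: list[Reaction]
    species: dict[str, Species] | None = None

    def resolved_species(self) -> dict[str, Species]:
        return self.species if self.species is not None else declare_species(self.reactions)


class MEModel:
    """Species, reactions with bounds, coupling constraints and an objective."""

    def __init__(self) -> None:
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.couplings: list[CouplingConstraint] = []
        self.objective_id: str = ""
        self.biomass_tags: BiomassTags | None = None
        self.units: list[MetabolicUnit] = []
        self.tu_info: dict[str, dict] = {}
        self.gene_index: dict[str, dict] = {}
        self.config: dict = {}

    # -- structure ---------------------------------------------------------
    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id}")
        self.reactions[rxn.id] = rxn

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        species_ids = list(self.species)
        sidx = {s: i for i, s in enumerate(species_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for s, c in rxn.stoichiometry.items():
                rows.append(sidx[s])
                cols.append(j)
                vals.append(c)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(species_ids), len(self.reactions))
        )
        return S, species_ids, self.reaction_ids

    def coupling_matrix(self) -> tuple[sparse.csr_matrix, list[str]]:
        """Inequality rows A v <= 0 encoding all coupling constraints."""
        ridx = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals, labels = [], [], [], []
        k = 0
        for cc in self.couplings:
            rows += [k, k]
            cols += [ridx[cc.v_use], ridx[cc.v_syn]]
            vals += [1.0, -cc.c_max]
            labels.append(f"{cc.name or cc.v_use}::upper")
            k += 1
            if cc.c_min > 0:
                rows += [k, k]
                cols += [ridx[cc.v_syn], ridx[cc.v_use]]
                vals += [cc.c_min, -1.0]
                labels.append(f"{cc.name or cc.v_use}::lower")
                k += 1
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(k, len(self.reactions)))
        return A, labels

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions.values()])
        ub = np.array([r.ub for r in self.reactions.values()])
        return lb, ub

    def copy(self) -> "MEModel":
        m = MEModel()
        m.species = dict(self.species)
        m.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        m.couplings = list(self.couplings)
        m.objective_id = self.objective_id
        m.biomass_tags = _copy.deepcopy(self.biomass_tags)
        m.units = list(self.units)
        m.tu_info = _copy.deepcopy(self.tu_info)
        m.gene_index = _copy.deepcopy(self.gene_index)
        m.config = _copy.deepcopy(self.config)
        return m

    # -- reports -----------------------------------------------------------
    def coefficient_magnitude_span(self) -> float:
        """log10 span of absolute stoichiometric coefficients (multiscale signature)."""
        vals = np.abs(self.stoichiometric_matrix()[0].data)
        vals = vals[vals > 0]
        return float(np.log10(vals.max()) - np.log10(vals.min()))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        def _num(x: float):
            return "inf" if x == INF else ("-inf" if x == -INF else x)

        payload = {
            "species": [
                {"id": s.id, "kind": s.kind, "compartment": s.compartment}
                for s in self.species.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                    "reversible": r.reversible,
                    "lb": _num(r.lb),
                    "ub": _num(r.ub),
                    "subsystem": r.subsystem,
                    "gpr": r.gpr,
                }
                for r in self.reactions.values()
            ],
            "couplings": [asdict(c) for c in self.couplings],
            "objective_id": self.objective_id,
            "biomass_tags": None
            if self.biomass_tags is None
            else {
                "aa_species": list(self.biomass_tags.aa_species),
                "gam": self.biomass_tags.gam,
                "gam_species": self.biomass_tags.gam_species,
            },
            "units": [asdict(u) for u in self.units],
            "tu_info": self.tu_info,
            "gene_index": self.gene_index,
            "config": self.config,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MEModel":
        def _num(x):
            return INF if x == "inf" else (-INF if x == "-inf" else float(x))

        data = json.loads(text)
        m = cls()
        for s in data["species"]:
            m.species[s["id"]] = Species(**s)
        for r in data["reactions"]:
            m.add_reaction(
                Reaction(
                    r["id"], r["stoichiometry"], r["reversible"],
                    _num(r["lb"]), _num(r["ub"]), r["subsystem"], r["gpr"],
                )
            )
        m.couplings = [CouplingConstraint(**c) for c in data["couplings"]]
        m.objective_id = data["objective_id"]
        if data["biomass_tags"]:
            bt = data["biomass_tags"]
            m.biomass_tags = BiomassTags(tuple(bt["aa_species"]), bt["gam"], bt["gam_species"])
        m.units = [
            MetabolicUnit(
                u["source_id"], u["enzyme_id"], tuple(u["module"]),
                tuple(u["reaction_ids"]), u["demand_id"], tuple(u["recycle_ids"]),
                u["directionality"],
            )
            for u in data["units"]
        ]
        m.tu_info = data["tu_info"]
        m.gene_index = data["gene_index"]
        m.config = data["config"]
        return m


# ---------------------------------------------------------------------------
# Assembly


def assemble(parts: list[ModelPart], objective_id: str = "") -> MEModel:
    """Union of reconstructions into one non-redundant ME model.

    Duplicate reaction ids are only tolerated for exchange reactions, where
    the first (metabolic-side) occurrence wins — list the metabolic part
    first.  Dangling species references raise with the offending ids.
    """
    model = MEModel()
    for part in parts:
        for sid, sp in part.resolved_species().items():
            model.species.setdefault(sid, sp)
        for rxn in part.reactions:
            if rxn.id in model.reactions:
                if rxn.is_exchange and model.reactions[rxn.id].is_exchange:
                    continue  # metabolic-side bounds win
                raise ValueError(f"duplicate non-exchange reaction id {rxn.id} in part {part.name}")
            model.add_reaction(rxn.copy())

    dangling = sorted(
        {s for r in model.reactions.values() for s in r.stoichiometry if s not in model.species}
    )
    if dangling:
        raise ValueError(f"reactions reference undeclared species: {dangling}")

    if objective_id:
        if objective_id not in model.reactions:
            raise ValueError(f"objective reaction {objective_id!r} not in model")
        model.objective_id = objective_id
    return model


def add_coupling(
    model: MEModel,
    v_syn: str,
    v_use: str,
    c_min: float = 1.0,
    c_max: float = 10000.0,
    name: str = "",
) -> MEModel:
    """Couple a synthesis flux to a utilization flux (see module docstring).

    Both reactions must be irreversible in the coupled direction (lb >= 0).
    """
    for rid in (v_syn, v_use):
        if rid not in model.reactions:
            raise ValueError(f"coupling references unknown reaction {rid!r}")
        if model.reactions[rid].lb < 0:
            raise ValueError(f"coupled reaction {rid!r} must have lb >= 0")
    model.couplings.append(CouplingConstraint(v_syn, v_use, c_min, c_max, name))
    return model


def mrna_coupling_coefficient(
    params: TranslationCouplingParams, mu: float = 1.0
) -> tuple[float, float]:
    """(c_min, c_max) translations permitted per mRNA before turnover.

    Evaluates k_translation * t_half / L at the lower (0.1 min) and upper
    (60 min) half-life bounds.  ``mu`` is the growth rate the translation
    rate refers to; the default parameterization uses a constant rate.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    k = params.rate_aa_per_s
    lo = k * params.t_half_min * 60.0 / params.length_aa
    hi = k * params.t_half_max * 60.0 / params.length_aa
    return lo, hi


def adjust_biomass(model: MEModel, adj: BiomassAdjustment) -> MEModel:
    """Scale the biomass amino-acid terms and the GAM; NTP terms untouched.

    Adjustments act on the current coefficients, so applying fractions f then
    g equals applying f*g.
    """
    tags = model.biomass_tags
    if tags is None or not model.objective_id:
        raise ValueError("biomass reaction is not tagged for adjustment")
    rxn = model.reactions[model.objective_id]
    for sp in tags.aa_species:
        if sp in rxn.stoichiometry:
            rxn.stoichiometry[sp] *= adj.aa_fraction
    removed = tags.gam * (1.0 - adj.gam_fraction)
    for sp, unit in tags.gam_species.items():
        new = rxn.stoichiometry.get(sp, 0.0) - unit * removed
        if new == 0:
            rxn.stoichiometry.pop(sp, None)
        else:
            rxn.stoichiometry[sp] = new
    tags.gam *= adj.gam_fraction
    rxn.stoichiometry = {s: c for s, c in rxn.stoichiometry.items() if c != 0}
    return model


# ---------------------------------------------------------------------------
# Media and transcription caps


def apply_media(model: MEModel, media: dict[str, float | tuple[float, float]]) -> MEModel:
    """Set exchange bounds: value -> (lb, ub) pair, or a bare lb (uptake limit)."""
    for ex_id, bounds in media.items():
        if ex_id not in model.reactions:
            raise ValueError(f"unknown exchange reaction {ex_id!r}")
        rxn = model.reactions[ex_id]
        if isinstance(bounds, (int, float)):
            rxn.lb = float(bounds)
        else:
            rxn.lb, rxn.ub = float(bounds[0]), float(bounds[1])
        rxn.reversible = rxn.lb < 0
    return model


def set_transcription_caps(
    model: MEModel,
    doubling_time_min: float = 24.0,
    stable_rate_nt_s: float = 85.0,
    mrna_rate_nt_s: float = 55.0,
    overrides: dict[str, float] | None = None,
) -> MEModel:
    """Cap each TU's transcription-initiation rate.

    ub = elongation_rate [nt/s] * 3600 / TU length [nt] * gene dosage, with
    the stable-RNA polymerase rate for stable TUs and the (slower) mRNA rate
    otherwise; rates correspond to fast growth (24 min doubling by default).
    ``overrides`` pins specific TUs to explicit caps (e.g. a deliberately
    binding rRNA bound).
    """
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be positive")
    overrides = overrides or {}
    for tu_id, info in model.tu_info.items():
        length = info["length"]
        if length <= 0:
            raise ValueError(f"TU {tu_id} has non-positive length")
        rate = stable_rate_nt_s if info["stable"] else mrna_rate_nt_s
        dosage = info.get("dosage", 1.0)
        ub = rate * 3600.0 / length * dosage
        if tu_id in overrides:
            ub = overrides[tu_id]
        model.reactions[info["ini_id"]].ub = ub
    return model


# ---------------------------------------------------------------------------
# Statistics


def reconstruction_statistics(model: MEModel) -> pd.DataFrame:
    """Per-subsystem reaction counts with a Total row (totals equal the sum)."""
    counts: dict[str, int] = {}
    for rxn in model.reactions.values():
        key = rxn.subsystem or "Unassigned"
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        {"subsystem": sorted(counts), "n_reactions": [counts[k] for k in sorted(counts)]}
    )
    total = int(df["n_reactions"].sum())
    df.loc[len(df)] = ["Total", total]
    return df


def load_reference_process_counts() -> pd.DataFrame:
    """The published genome-scale reconstruction's 26 per-process reaction counts."""
    with resources.files("memodel.data").joinpath("me_matrix_process_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def verify_process_counts(df: pd.DataFrame) -> tuple[int, int, bool]:
    """Sum the per-process counts and compare with the stated total."""
    body = df[df["cellular_process"] != "Total"]
    total_row = df[df["cellular_process"] == "Total"]
    computed = int(body["n_reactions"].sum())
    stated = int(total_row["n_reactions"].iloc[0])
    return computed, stated, computed == stated


def base_medium(free_uptake: float = 1000.0) -> dict[str, tuple[float, float]]:
    """The base-medium ion exchanges, opened at the free-uptake rate."""
    with resources.files("memodel.data").joinpath("base_medium.tsv").open() as fh:
        ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    return {ex: (-free_uptake, INF) for ex in ids}


def load_media(path: str | Path) -> dict[str, tuple[float, float]]:
    """Media file: TSV with columns exchange_id, lb[, ub] or a JSON object."""
    p = Path(path)
    if p.suffix == ".json":
        raw = json.loads(p.read_text())
        return {k: (float(v[0]), float(v[1])) if isinstance(v, list) else (float(v), INF) for k, v in raw.items()}
    df = pd.read_csv(p, sep="\t")
    out = {}
    for _, row in df.iterrows():
        ub = float(row["ub"]) if "ub" in df.columns and not pd.isna(row.get("ub")) else INF
        out[str(row["exchange_id"])] = (float(row["lb"]), ub)
    return out
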