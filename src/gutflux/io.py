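"""Readers and writers for all file dialects, run configuration, and the
end-to-end pipeline.

Formats:

* JSON model dialect — the package's native, lossless model serialisation
  (compartments, metabolites, reactions, objective, couplings, metadata).
* SBML Level 3 core subset — flux bounds through fbc parameters, objective
  through the fbc extension, reaction kinds through SBO terms; identifiers
  are escaped with the ``__<charcode>__`` convention so arbitrary ids
  round-trip. Unsupported constructs raise instead of being dropped.
* Abundance TSV — ``Genome<TAB>Relative Abundance (%)``; percent values
  become fractions, an ``unmapped`` row is dropped and logged.
* Diet, intake, composition, molar-mass, clinical and result tables — plain
  TSV/CSV, UTF-8, ``#``-prefixed metadata lines, 6 significant digits by
  default (full precision on request).

All writers are parseable by their paired readers, and repeated runs with
the same inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import libsbml
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    AbundanceProfile,
    CommunityConfig,
    CommunityModel,
    StrainRecord,
    SupplementPolicy,
    apply_diet,
    assemble_community,
    filter_and_renormalize,
)
from .core import (
    CouplingConstraint,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .diet import DietFluxVector, FoodIntakeTable, NutrientCompositionTable
from .pipeline import (
    ContributionRecord,
    NetFluxRecord,
    classify_exchange_roles,
    shannon,
    simulate_sample,
    strain_contributions,
    subsystem_totals,
)
from .stats import ClinicalSeries, build_network, correlate_features

__all__ = [
    "RunConfig",
    "read_model",
    "write_model",
    "model_to_dict",
    "model_from_dict",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_diet_tsv",
    "write_diet_tsv",
    "read_intake_tsv",
    "read_composition_tsv",
    "read_molar_mass_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "write_net_flux_tsv",
    "write_contributions_tsv",
    "write_subsystem_tsv",
    "write_edges_tsv",
    "run_pipeline",
    "PIPELINE_STAGES",
]

logger = logging.getLogger(__name__)

PIPELINE_STAGES = (
    "filter", "assemble", "diet", "simulate", "classify", "subsystem",
    "contributions", "correlate", "network",
)


def _fmt(value: float, full_precision: bool = False) -> str:
    value = float(value)
    if value == 0.0:
        value = 0.0  # normalise -0.0
    if full_precision:
        return repr(value)
    return format(value, ".6g")


# ---------------------------------------------------------------------------
# JSON model dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    doc = {
        "id": model.id,
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [
            {
                "id": met.id,
                "compartment": met.compartment,
                "name": met.name,
                "subsystem": met.subsystem,
            }
            for key in sorted(model.metabolites)
            for met in [model.metabolites[key]]
        ],
        "reactions": [
            {
                "id": rxn.id,
                "stoichiometry": [
                    [mid, comp, coef]
                    for (mid, comp), coef in sorted(rxn.stoichiometry.items())
                ],
                "lb": rxn.lb,
                "ub": rxn.ub,
                "kind": rxn.kind,
            }
            for rid in sorted(model.reactions)
            for rxn in [model.reactions[rid]]
        ],
        "objective": dict(sorted(model.objective.items())),
        "couplings": [
            {
                "coupled_reaction": c.coupled_reaction,
                "anchor_reaction": c.anchor_reaction,
                "factor": c.factor,
                "slack": c.slack,
            }
            for c in model.couplings
        ],
        "metadata": model.metadata,
    }
    if isinstance(model, CommunityModel):
        doc["strain_registry"] = {
            strain: {
                "compartment": rec.compartment,
                "reaction_ids": rec.reaction_ids,
                "biomass_reaction": rec.biomass_reaction,
                "iex_reactions": rec.iex_reactions,
                "abundance": rec.abundance,
            }
            for strain, rec in sorted(model.strain_registry.items())
        }
    return doc


def model_from_dict(doc: dict) -> MetabolicModel:
    cls = CommunityModel if "strain_registry" in doc else MetabolicModel
    model = cls(id=doc["id"])
    for tag, name in doc.get("compartments", {}).items():
        model.add_compartment(tag, name)
    for entry in doc.get("metabolites", []):
        model.add_metabolite(Metabolite(
            entry["id"], entry["compartment"],
            entry.get("name", ""), entry.get("subsystem", "other"),
        ))
    for entry in doc.get("reactions", []):
        model.add_reaction(Reaction(
            entry["id"],
            {(mid, comp): float(coef)
             for mid, comp, coef in entry["stoichiometry"]},
            lb=float(entry["lb"]), ub=float(entry["ub"]),
            kind=entry.get("kind", "internal"),
        ))
    model.objective = {
        rid: float(c) for rid, c in doc.get("objective", {}).items()
    }
    model.couplings = [
        CouplingConstraint(
            c["coupled_reaction"], c["anchor_reaction"],
            float(c["factor"]), float(c["slack"]),
        )
        for c in doc.get("couplings", [])
    ]
    model.metadata = dict(doc.get("metadata", {}))
    if isinstance(model, CommunityModel):
        model.strain_registry = {
            strain: StrainRecord(
                compartment=rec["compartment"],
                reaction_ids=list(rec["reaction_ids"]),
                biomass_reaction=rec["biomass_reaction"],
                iex_reactions=dict(rec["iex_reactions"]),
                abundance=float(rec["abundance"]),
            )
            for strain, rec in doc["strain_registry"].items()
        }
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML subset
# ---------------------------------------------------------------------------

_SBO_OF_KIND = {
    "internal": "SBO:0000176",
    "exchange": "SBO:0000627",
    "transport": "SBO:0000185",
    "biomass": "SBO:0000629",
}
_KIND_OF_SBO = {v: k for k, v in _SBO_OF_KIND.items()}


def _escape(raw: str) -> str:
    return re.sub(r"[^0-9a-zA-Z_]", lambda m: f"__{ord(m.group())}__", raw)


def _unescape(sid: str) -> str:
    return re.sub(r"__(\d+)__", lambda m: chr(int(m.group(1))), sid)


def _notes(lines: list[str]) -> str:
    body = "".join(f"<p>{line}</p>" for line in lines)
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _notes_lines(node) -> list[str]:
    if not node.isSetNotes():
        return []
    text = node.getNotesString()
    return re.findall(r"<p>(.*?)</p>", text, flags=re.S)


class SBMLDialectError(ValueError):
    """The SBML file uses constructs outside the supported subset."""


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId("Mo_" + _escape(model.id))
    sm.setName(model.id)
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(False)
    for tag in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId("C_" + _escape(tag))
        comp.setName(model.compartments[tag])
        comp.setConstant(True)
    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        sp = sm.createSpecies()
        sp.setId("M_" + _escape(met.id) + "_" + _escape(met.compartment))
        sp.setName(met.name)
        sp.setCompartment("C_" + _escape(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setNotes(_notes([f"subsystem: {met.subsystem}"]))
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        for suffix, value in (("lb", rxn.lb), ("ub", rxn.ub)):
            par = sm.createParameter()
            par.setId("P_" + _escape(rid) + f"_{suffix}")
            par.setValue(float(value))
            par.setConstant(True)
        sr = sm.createReaction()
        sr.setId("R_" + _escape(rid))
        sr.setName(rid)
        sr.setFast(False)
        sr.setReversible(rxn.lb < 0)
        sr.setSBOTerm(_SBO_OF_KIND[rxn.kind])
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound("P_" + _escape(rid) + "_lb")
        rfbc.setUpperFluxBound("P_" + _escape(rid) + "_ub")
        for (mid, comp), coef in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies("M_" + _escape(mid) + "_" + _escape(comp))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fbc.setActiveObjectiveId("obj")
        for rid in sorted(model.objective):
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + _escape(rid))
            fo.setCoefficient(float(model.objective[rid]))
    lines = [
        "coupling: {}|{}|{!r}|{!r}".format(
            c.coupled_reaction, c.anchor_reaction, c.factor, c.slack)
        for c in model.couplings
    ]
    if lines:
        sm.setNotes(_notes(lines))
    libsbml.writeSBMLToFile(doc, str(path))


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SBMLDialectError(
            f"{path}: {doc.getError(0).getMessage().strip()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLDialectError(f"{path}: file contains no model")
    for attr, label in (
        ("getNumRules", "rules"), ("getNumEvents", "events"),
        ("getNumConstraints", "constraints"),
        ("getNumInitialAssignments", "initial assignments"),
    ):
        if getattr(sm, attr)() > 0:
            raise SBMLDialectError(
                f"{path}: SBML {label} are outside the supported subset"
            )
    model_id = sm.getName() or _unescape(sm.getId()[3:])
    model = MetabolicModel(id=model_id)
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        tag = _unescape(comp.getId()[2:])
        model.add_compartment(tag, comp.getName() or tag)
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        tag = _unescape(sp.getCompartment()[2:])
        suffix = "_" + _escape(tag)
        sid = sp.getId()[2:]
        if not sid.endswith(suffix):
            raise SBMLDialectError(
                f"{path}: species id {sp.getId()!r} does not follow the "
                "M_<id>_<compartment> convention"
            )
        mid = _unescape(sid[: -len(suffix)])
        subsystem = "other"
        for line in _notes_lines(sp):
            if line.startswith("subsystem: "):
                subsystem = line[len("subsystem: "):].strip()
        model.add_metabolite(Metabolite(mid, tag, sp.getName(), subsystem))
    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _unescape(sr.getId()[2:])
        rfbc = sr.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound():
            raise SBMLDialectError(
                f"{path}: reaction {rid!r} lacks fbc flux bounds; only the "
                "fbc bound convention is supported"
            )
        lb = params[rfbc.getLowerFluxBound()]
        ub = params[rfbc.getUpperFluxBound()]
        stoich: dict[tuple[str, str], float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sp = sm.getSpecies(ref.getSpecies())
            tag = _unescape(sp.getCompartment()[2:])
            mid = _unescape(ref.getSpecies()[2:][: -len("_" + _escape(tag))])
            stoich[(mid, tag)] = stoich.get((mid, tag), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sp = sm.getSpecies(ref.getSpecies())
            tag = _unescape(sp.getCompartment()[2:])
            mid = _unescape(ref.getSpecies()[2:][: -len("_" + _escape(tag))])
            stoich[(mid, tag)] = stoich.get((mid, tag), 0.0) + ref.getStoichiometry()
        kind = "internal"
        if sr.isSetSBOTerm():
            kind = _KIND_OF_SBO.get(sr.getSBOTermID(), "internal")
        model.add_reaction(Reaction(rid, stoich, lb=lb, ub=ub, kind=kind))
    mfbc = sm.getPlugin("fbc")
    if mfbc is not None and mfbc.getNumObjectives() > 0:
        obj = mfbc.getObjective(mfbc.getActiveObjectiveId()) or \
            mfbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            model.objective[_unescape(fo.getReaction()[2:])] = \
                fo.getCoefficient()
    for line in _notes_lines(sm):
        if line.startswith("coupling: "):
            coupled, anchor, c, u = line[len("coupling: "):].split("|")
            model.couplings.append(
                CouplingConstraint(coupled, anchor, float(c), float(u))
            )
    model.validate()
    return model


def read_model(path: str | Path) -> MetabolicModel:
    """Read a model from the JSON dialect or the SBML subset (by suffix)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as err:
                raise ValueError(f"{path}: malformed JSON: {err}") from err
        return model_from_dict(doc)
    if path.suffix in (".xml", ".sbml"):
        return _read_sbml(path)
    raise ValueError(f"{path}: unknown model format {path.suffix!r}")


def write_model(model: MetabolicModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if path.suffix in (".xml", ".sbml"):
        _write_sbml(model, path)
        return
    raise ValueError(f"{path}: unknown model format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Tabular dialects
# ---------------------------------------------------------------------------

ABUNDANCE_COLUMNS = ("Genome", "Relative Abundance (%)")


def read_abundance_tsv(path: str | Path,
                       sample_id: str | None = None) -> AbundanceProfile:
    """Read a per-sample abundance table (percent values -> fractions)."""
    path = Path(path)
    abundances: dict[str, float] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for col in ABUNDANCE_COLUMNS:
                    if col not in header:
                        raise ValueError(
                            f"{path}:{lineno}: missing column {col!r}"
                        )
                g = header.index(ABUNDANCE_COLUMNS[0])
                a = header.index(ABUNDANCE_COLUMNS[1])
                continue
            strain = cells[g].strip()
            if strain.lower() == "unmapped":
                logger.info("%s:%d: dropped 'unmapped' row", path, lineno)
                continue
            try:
                percent = float(cells[a])
            except (ValueError, IndexError) as err:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric abundance for "
                    f"{strain!r}"
                ) from err
            if strain in abundances:
                raise ValueError(
                    f"{path}:{lineno}: duplicate strain row {strain!r}"
                )
            abundances[strain] = percent / 100.0
    if header is None:
        raise ValueError(f"{path}: empty abundance table")
    return AbundanceProfile(
        sample_id=sample_id or path.stem, abundances=abundances,
    )


def write_abundance_tsv(profile: AbundanceProfile, path: str | Path,
                        full_precision: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample: {profile.sample_id}\n")
        fh.write("\t".join(ABUNDANCE_COLUMNS) + "\n")
        for strain in profile.strains():
            pct = profile.abundances[strain] * 100.0
            fh.write(f"{strain}\t{_fmt(pct, full_precision)}\n")


def read_diet_tsv(path: str | Path) -> DietFluxVector:
    """Diet table: metabolite id (or ``EX_<m>[d]``) and flux in mmol/day."""
    path = Path(path)
    fluxes: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 or cells[0] in ("metabolite", "reaction"):
                if not _is_number(cells[-1]):
                    continue  # header
            met = cells[0].strip()
            m = re.fullmatch(r"EX_(.+)\[d\]", met)
            if m:
                met = m.group(1)
            try:
                flux = float(cells[1])
            except (ValueError, IndexError) as err:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric flux for {met!r}"
                ) from err
            fluxes[met] = flux
    return DietFluxVector(fluxes)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def write_diet_tsv(diet: DietFluxVector, path: str | Path,
                   full_precision: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite\tflux_mmol_per_day\n")
        for met, flux in diet.items():
            fh.write(f"{met}\t{_fmt(flux, full_precision)}\n")


def read_intake_tsv(path: str | Path) -> FoodIntakeTable:
    """Food-intake table: columns ``formula``, ``food``, then one column per
    period (grams/day)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"formula", "food"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: intake table needs columns {required}")
    periods = [c for c in frame.columns if c not in required]
    table = FoodIntakeTable()
    for _, row in frame.iterrows():
        for period in periods:
            table.add(str(row["food"]), period, float(row[period]))
    return table


def read_composition_tsv(path: str | Path) -> NutrientCompositionTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    table = NutrientCompositionTable()
    for _, row in frame.iterrows():
        table.set(str(row["food"]), str(row["metabolite"]),
                  float(row["fraction"]))
    return table


def read_molar_mass_tsv(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(row["metabolite"]): float(row["molar_mass"])
        for _, row in frame.iterrows()
    }


def read_clinical_csv(path: str | Path) -> ClinicalSeries:
    frame = pd.read_csv(path, comment="#", index_col=0)
    return ClinicalSeries(
        timepoints=[str(t) for t in frame.index],
        parameters={
            str(col): [float(v) for v in frame[col]]
            for col in frame.columns
        },
    )


def write_clinical_csv(clinical: ClinicalSeries, path: str | Path) -> None:
    frame = clinical.to_frame()
    frame.index.name = "timepoint"
    frame.to_csv(path)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_net_flux_tsv(records: list[NetFluxRecord], path: str | Path,
                       full_precision: bool = False) -> None:
    cols = ("sample", "metabolite", "max_secretion", "min_secretion",
            "max_uptake", "min_uptake", "net_secretion", "net_uptake")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# net metabolite fluxes, mmol/day; uptake fluxes signed "
                 "(diet exchange, <= 0)\n")
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.sample_id, r.metabolite,
                _fmt(r.max_secretion, full_precision),
                _fmt(r.min_secretion, full_precision),
                _fmt(r.max_uptake, full_precision),
                _fmt(r.min_uptake, full_precision),
                _fmt(r.net_secretion, full_precision),
                _fmt(r.net_uptake, full_precision),
            ]) + "\n")


def read_net_flux_tsv(path: str | Path) -> list[NetFluxRecord]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        NetFluxRecord(
            sample_id=str(r["sample"]), metabolite=str(r["metabolite"]),
            max_secretion=float(r["max_secretion"]),
            min_secretion=float(r["min_secretion"]),
            max_uptake=float(r["max_uptake"]),
            min_uptake=float(r["min_uptake"]),
            net_secretion=float(r["net_secretion"]),
            net_uptake=float(r["net_uptake"]),
        )
        for _, r in frame.iterrows()
    ]


def write_contributions_tsv(records: list[ContributionRecord],
                            path: str | Path,
                            full_precision: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# per-strain attainable IEX secretion, mmol/day\n")
        fh.write("sample\tmetabolite\tstrain\tmin_flux\tmax_flux\tshare\n")
        for r in records:
            fh.write("\t".join([
                r.sample_id, r.metabolite, r.strain,
                _fmt(r.min_flux, full_precision),
                _fmt(r.max_flux, full_precision),
                _fmt(r.share, full_precision),
            ]) + "\n")


def write_subsystem_tsv(summary: dict, path: str | Path,
                        full_precision: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# summed positive net secretion per metabolism subsystem, "
                 "mmol/day\n")
        fh.write("sample\tsubsystem\tnet_secretion\n")
        for sample in summary:
            for sub in sorted(summary[sample]):
                fh.write(f"{sample}\t{sub}\t"
                         f"{_fmt(summary[sample][sub], full_precision)}\n")


def write_edges_tsv(edges, path: str | Path,
                    full_precision: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Spearman correlation edges passing |rho| and FDR "
                 "thresholds\n")
        fh.write("metabolite\tclinical\trho\tp_raw\tp_fdr\tsign\n")
        for e in edges:
            fh.write("\t".join([
                e.feature_a, e.feature_b,
                _fmt(e.rho, full_precision),
                _fmt(e.p_raw, full_precision),
                _fmt(e.p_fdr, full_precision),
                "+" if e.sign > 0 else "-",
            ]) + "\n")


def write_roles_tsv(roles: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# exchange role across all samples\n")
        fh.write("metabolite\trole\n")
        for met in sorted(roles):
            fh.write(f"{met}\t{roles[met]}\n")


def write_diversity_tsv(values: dict[str, float], path: str | Path,
                        full_precision: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Shannon alpha diversity of the filtered profile\n")
        fh.write("sample\tshannon\n")
        for sample, h in values.items():
            fh.write(f"{sample}\t{_fmt(h, full_precision)}\n")


# ---------------------------------------------------------------------------
# Run configuration and the pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    models_dir: str = "models"
    abundance_dir: str = "abundance"
    diet_path: str = "diet.tsv"
    clinical_path: str = "clinical.csv"
    out_dir: str = "results"
    cutoff: float = 0.001
    coupling_factor: float = 400.0
    coupling_slack: float = 0.01
    biomass_lb: float = 0.4
    biomass_ub: float = 1.0
    objective_fraction: float = 0.9999
    r_thresh: float = 0.7
    p_thresh: float = 0.1
    supplement_epsilon: float = 0.0
    essential_metabolites: list[str] = field(default_factory=list)
    seed: int = 0
    full_precision: bool = False

    def community_config(self) -> CommunityConfig:
        supplement = None
        if self.supplement_epsilon > 0 and self.essential_metabolites:
            supplement = SupplementPolicy(
                essential=list(self.essential_metabolites),
                epsilon=self.supplement_epsilon,
            )
        return CommunityConfig(
            cutoff=self.cutoff,
            coupling_factor=self.coupling_factor,
            coupling_slack=self.coupling_slack,
            biomass_bounds=(self.biomass_lb, self.biomass_ub),
            objective_fraction=self.objective_fraction,
            supplement=supplement,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_scenario(bundle, directory: str | Path,
                   config: "RunConfig | None" = None) -> Path:
    """Write a synthetic scenario as a ready-to-run input directory.

    Layout: ``models/*.json``, ``abundance/*.tsv``, ``diet.tsv``,
    ``clinical.csv``, ``truth.json`` and a ``config.yaml`` whose paths
    point at those files.
    """
    directory = Path(directory)
    (directory / "models").mkdir(parents=True, exist_ok=True)
    (directory / "abundance").mkdir(parents=True, exist_ok=True)
    for strain in sorted(bundle.models):
        write_model(bundle.models[strain], directory / "models" / f"{strain}.json")
    for profile in bundle.profiles:
        write_abundance_tsv(profile,
                            directory / "abundance" / f"{profile.sample_id}.tsv")
    write_diet_tsv(bundle.diet, directory / "diet.tsv")
    write_clinical_csv(bundle.clinical, directory / "clinical.csv")
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = config or RunConfig(
        cutoff=bundle.config.cutoff,
        coupling_factor=bundle.config.coupling_factor,
        coupling_slack=bundle.config.coupling_slack,
        biomass_lb=bundle.config.biomass_bounds[0],
        biomass_ub=bundle.config.biomass_bounds[1],
        objective_fraction=bundle.config.objective_fraction,
        seed=bundle.seed,
    )
    cfg.to_yaml(directory / "config.yaml")
    return directory


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> Path:
    """Execute filter -> assemble -> diet -> simulate -> classify ->
    subsystem -> contributions -> correlate -> network and write all
    outputs plus a machine-readable manifest. Idempotent for fixed inputs
    and configuration."""
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ccfg = config.community_config()
    completed: list[str] = []
    notes: list[str] = []

    def _stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as err:
                raise PipelineError(name, str(err)) from err
            completed.append(name)
            return result
        return deco

    models_dir = base / config.models_dir
    abundance_dir = base / config.abundance_dir
    model_paths = sorted(models_dir.glob("*.json")) + \
        sorted(models_dir.glob("*.xml"))
    if not model_paths:
        raise PipelineError("filter", f"no models found in {models_dir}")
    models = {m.id: m for m in (read_model(p) for p in model_paths)}
    abundance_paths = sorted(abundance_dir.glob("*.tsv"))
    if not abundance_paths:
        raise PipelineError("filter", f"no abundance tables in {abundance_dir}")
    raw_profiles = [read_abundance_tsv(p) for p in abundance_paths]
    if not Path(base / config.diet_path).exists():
        raise PipelineError("diet", f"missing diet table {config.diet_path}")
    diet = read_diet_tsv(base / config.diet_path)

    @_stage("filter")
    def profiles():
        return [filter_and_renormalize(p, config.cutoff) for p in raw_profiles]

    @_stage("assemble")
    def communities():
        return {
            p.sample_id: assemble_community(models, p, ccfg) for p in profiles
        }

    @_stage("diet")
    def fed():
        return {
            sample: apply_diet(community, diet, ccfg.supplement)
            for sample, community in communities.items()
        }

    @_stage("simulate")
    def net_records():
        records: list[NetFluxRecord] = []
        for sample in sorted(fed):
            records.extend(simulate_sample(fed[sample], None, ccfg))
        write_net_flux_tsv(records, out / "net_fluxes.tsv",
                           config.full_precision)
        diversity = {p.sample_id: shannon(p) for p in profiles}
        write_diversity_tsv(diversity, out / "diversity.tsv",
                            config.full_precision)
        return records

    @_stage("classify")
    def roles():
        result = classify_exchange_roles(net_records)
        write_roles_tsv(result, out / "roles.tsv")
        return result

    @_stage("subsystem")
    def subsystems():
        subsystem_map = {}
        for model in models.values():
            for met in model.metabolites.values():
                subsystem_map.setdefault(met.id, met.subsystem)
        summary = subsystem_totals(net_records, subsystem_map)
        write_subsystem_tsv(summary, out / "subsystems.tsv",
                            config.full_precision)
        return summary

    @_stage("contributions")
    def contributions():
        secreted = sorted({
            r.metabolite for r in net_records if r.net_secretion > 1e-6
        })
        records: list[ContributionRecord] = []
        for sample in sorted(fed):
            for met in secreted:
                records.extend(
                    strain_contributions(fed[sample], None, met, ccfg)
                )
        write_contributions_tsv(records, out / "contributions.tsv",
                                config.full_precision)
        return records

    clinical_path = base / config.clinical_path
    if not clinical_path.exists():
        raise PipelineError(
            "correlate", f"missing clinical table {config.clinical_path}"
        )

    @_stage("correlate")
    def edges():
        clinical = read_clinical_csv(clinical_path)
        table = pd.DataFrame(
            {
                met: {
                    r.sample_id: r.net_secretion
                    for r in net_records if r.metabolite == met
                }
                for met in sorted({r.metabolite for r in net_records})
            }
        ).loc[[str(t) for t in clinical.timepoints]]
        return correlate_features(
            table, clinical, r_thresh=config.r_thresh,
            p_thresh=config.p_thresh,
        )

    @_stage("network")
    def graph():
        write_edges_tsv(edges, out / "edges.tsv", config.full_precision)
        # average share across samples per (metabolite, strain)
        pooled: dict[tuple[str, str], list[float]] = {}
        for rec in contributions:
            pooled.setdefault((rec.metabolite, rec.strain), []).append(
                rec.share)
        mean_contribs = [
            ContributionRecord(
                sample_id="all", metabolite=met, strain=strain,
                min_flux=float("nan"), max_flux=float("nan"),
                share=float(np.mean(shares)),
            )
            for (met, strain), shares in sorted(pooled.items())
        ]
        g = build_network(edges, mean_contribs)
        import networkx as nx

        nx.write_graphml(g, out / "network.graphml")
        return g

    manifest = {
        "package": "gutflux",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages_completed": completed,
        "n_samples": len(profiles),
        "n_models": len(models),
        "n_net_flux_records": len(net_records),
        "n_edges": len(edges),
        "notes": notes,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
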