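"""Reading and writing reconstructions: SBML L3+fbc and a tabular dialect.

The tabular dialect is two delimited UTF-8 files with a mandatory header row:

``metabolites``: columns ``id``, ``name`` (optional), ``compartment``,
``formula`` (optional).

``reactions``: columns ``id``, ``equation``, ``lb``, ``ub``, plus optional
``name`` and ``gene_rule``.  Equations use explicit coefficients and one of
the arrow tokens ``->`` (irreversible), ``<-`` (irreversible, written right
to left) or ``<=>`` (reversible), e.g. ``A + 2 B <=> C``.  An empty side
denotes an exchange with the environment (``-> A`` is uptake of A).

Assembled whole-plant models are written to SBML with tissue, period and
pool identity encoded in the id and compartment suffixes, so the file is
self-describing and can be read back with :func:`read_plant_sbml`.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import libsbml

from .core import (
    DEFAULT_BOUND,
    SEP,
    BaseGEM,
    Column,
    FluxInfo,
    Metabolite,
    ModelError,
    Reaction,
    RowInfo,
    ROW_COMMON_POOL,
    ROW_STORAGE_POOL,
    ROW_TISSUE,
    WholePlantModel,
)

__all__ = [
    "read_sbml",
    "write_sbml",
    "read_table",
    "read_plant_sbml",
    "parse_equation",
]


class SBMLReadError(IOError):
    """Parse or validation failure, carrying the SBML error message."""


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "->", "<-")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into signed stoichiometry.

    Returns ``(stoichiometry, reversible)``.  Substrates carry negative
    coefficients.  Raises :class:`ModelError` naming the offending token.
    """
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ModelError(f"equation {text!r}: no arrow token (->, <-, <=>)")
    left, right = text.split(arrow, 1)
    if arrow == "<-":
        left, right = right, left
    stoich: dict[str, float] = {}

    def _add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            tokens = term.split()
            if len(tokens) == 1:
                coef, met = 1.0, tokens[0]
            elif len(tokens) == 2:
                try:
                    coef = float(tokens[0])
                except ValueError:
                    raise ModelError(
                        f"equation {text!r}: bad coefficient {tokens[0]!r}"
                    ) from None
                met = tokens[1]
            else:
                raise ModelError(f"equation {text!r}: malformed term {term.strip()!r}")
            if not met or any(a in met for a in _ARROWS):
                raise ModelError(f"equation {text!r}: malformed term {term.strip()!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    _add(left, -1.0)
    _add(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelError(f"equation {text!r}: empty or fully cancelling equation")
    return stoich, arrow == "<=>"


def _sniff_reader(path: str | Path):
    with open(path, newline="", encoding="utf-8") as handle:
        sample = handle.read()
    delim = "\t" if "\t" in sample.splitlines()[0] else ","
    return csv.DictReader(sample.splitlines(), delimiter=delim)


def read_table(reactions_path: str | Path, metabolites_path: str | Path) -> BaseGEM:
    """Read the tabular dialect (see module docstring) into a BaseGEM."""
    metabolites = []
    for row in _sniff_reader(metabolites_path):
        metabolites.append(
            Metabolite(
                id=row["id"].strip(),
                name=(row.get("name") or "").strip(),
                compartment=(row.get("compartment") or "c").strip(),
                formula=(row.get("formula") or None),
            )
        )
    reactions = []
    for lineno, row in enumerate(_sniff_reader(reactions_path), start=2):
        try:
            stoich, reversible = parse_equation(row["equation"])
            lb = float(row["lb"]) if row.get("lb", "") != "" else (
                -DEFAULT_BOUND if reversible else 0.0
            )
            ub = float(row["ub"]) if row.get("ub", "") != "" else DEFAULT_BOUND
            if reversible and lb >= 0 and row.get("lb", "") == "":
                lb = -DEFAULT_BOUND
            reactions.append(
                Reaction(
                    id=row["id"].strip(),
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    name=(row.get("name") or "").strip(),
                    is_exchange=len(stoich) == 1,
                    gene_rule=(row.get("gene_rule") or None),
                )
            )
        except (ModelError, KeyError, ValueError) as exc:
            raise ModelError(f"{reactions_path}, line {lineno}: {exc}") from exc
    return BaseGEM(metabolites, reactions)


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def _check_sbml_errors(doc: libsbml.SBMLDocument, path) -> None:
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLReadError(f"{path}: {err.getMessage().strip()}")


def _reaction_bounds(model, rxn) -> tuple[float | None, float | None]:
    """Bounds from fbc attributes, else kinetic-law parameters, else None."""
    fbc = rxn.getPlugin("fbc")
    lb = ub = None
    if fbc is not None:
        for attr, setter in (("getLowerFluxBound", "lb"), ("getUpperFluxBound", "ub")):
            pid = getattr(fbc, attr)()
            if pid:
                param = model.getParameter(pid)
                if param is not None:
                    if setter == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
    if (lb is None or ub is None) and rxn.isSetKineticLaw():
        law = rxn.getKineticLaw()
        for j in range(law.getNumParameters()):
            p = law.getParameter(j)
            if p.getId() == "LOWER_BOUND" and lb is None:
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND" and ub is None:
                ub = p.getValue()
    return lb, ub


def read_sbml(path: str | Path) -> BaseGEM:
    """Read an SBML (L2 or L3, with fbc or kinetic-law bounds) reconstruction.

    Species flagged ``boundaryCondition`` are treated as environment sinks:
    they are excluded from the mass-balance rows and any reaction touching
    them becomes an exchange.  Reactions without declared bounds receive the
    COBRA defaults (0 or -1000, +1000) with a warning.
    """
    path = str(path)
    doc = libsbml.readSBMLFromFile(path)
    _check_sbml_errors(doc, path)
    model = doc.getModel()
    if model is None:
        raise SBMLReadError(f"{path}: no model element")

    boundary: set[str] = set()
    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=_species_formula(sp),
            )
        )

    reactions = []
    missing_bounds = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, float] = {}
        touched_boundary = False
        for ref, sign in _iter_species_refs(rxn):
            sid = ref.getSpecies()
            if sid in boundary:
                touched_boundary = True
                continue
            coef = ref.getStoichiometry()
            if coef == 0:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + sign * coef
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            raise ModelError(
                f"{path}: reaction {rxn.getId()!r} has no internal metabolites"
            )
        lb, ub = _reaction_bounds(model, rxn)
        if lb is None or ub is None:
            missing_bounds.append(rxn.getId())
            rev = rxn.getReversible()
            lb = -DEFAULT_BOUND if rev else 0.0 if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rxn.getName() or "",
                is_exchange=len(stoich) == 1 or touched_boundary,
                gene_rule=_gene_rule(rxn),
            )
        )
    if missing_bounds:
        warnings.warn(
            f"{len(missing_bounds)} reaction(s) without declared bounds received "
            f"defaults (first: {missing_bounds[0]!r})",
            stacklevel=2,
        )
    annotations = {"source": path}
    if model.getId():
        annotations["model_id"] = model.getId()
    return BaseGEM(metabolites, reactions, annotations)


def _iter_species_refs(rxn):
    for j in range(rxn.getNumReactants()):
        yield rxn.getReactant(j), -1.0
    for j in range(rxn.getNumProducts()):
        yield rxn.getProduct(j), +1.0


def _species_formula(sp) -> str | None:
    fbc = sp.getPlugin("fbc")
    if fbc is not None and fbc.isSetChemicalFormula():
        return fbc.getChemicalFormula()
    return None


def _gene_rule(rxn) -> str | None:
    fbc = rxn.getPlugin("fbc")
    if fbc is not None and fbc.isSetGeneProductAssociation():
        assoc = fbc.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            return libsbml.FbcAssociation_toInfix(assoc) or None
    return None


# -- writing ----------------------------------------------------------------


def _new_document() -> tuple[libsbml.SBMLDocument, libsbml.Model]:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.getPlugin("fbc").setStrict(True)
    return doc, model


def _add_compartment(model, comp_id: str, seen: set[str]) -> None:
    if comp_id in seen:
        return
    comp = model.createCompartment()
    comp.setId(comp_id)
    comp.setConstant(True)
    seen.add(comp_id)


def _add_species(model, sid: str, comp_id: str) -> None:
    sp = model.createSpecies()
    sp.setId(sid)
    sp.setCompartment(comp_id)
    sp.setHasOnlySubstanceUnits(False)
    sp.setBoundaryCondition(False)
    sp.setConstant(False)


_bound_cache: dict = {}


def _bound_param(model, value: float, cache: dict[float, str]) -> str:
    if value not in cache:
        pid = f"bnd_{len(cache)}"
        param = model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        cache[value] = pid
    return cache[value]


def _add_reaction(model, rid, stoich, lb, ub, cache, name="") -> None:
    rxn = model.createReaction()
    rxn.setId(rid)
    if name:
        rxn.setName(name)
    rxn.setReversible(lb < 0)
    rxn.setFast(False)
    for met, coef in stoich.items():
        ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
        ref.setSpecies(met)
        ref.setStoichiometry(abs(coef))
        ref.setConstant(True)
    fbc = rxn.getPlugin("fbc")
    fbc.setLowerFluxBound(_bound_param(model, lb, cache))
    fbc.setUpperFluxBound(_bound_param(model, ub, cache))


def write_sbml(model: BaseGEM | WholePlantModel, path: str | Path) -> None:
    """Write a base or assembled model as SBML L3 + fbc.

    For a :class:`WholePlantModel` the tissue/period/pool identity is kept in
    the id and compartment suffixes, and the photon objective is written as
    the fbc (minimize) objective.
    """
    if isinstance(model, WholePlantModel):
        _write_plant_sbml(model, path)
        return
    if not model.metabolites or not model.reactions:
        raise ModelError("refusing to write an empty model")
    doc, sbml_model = _new_document()
    sbml_model.setId(model.annotations.get("model_id", "base_gem"))
    seen: set[str] = set()
    cache: dict[float, str] = {}
    for met in model.metabolites:
        _add_compartment(sbml_model, met.compartment, seen)
        _add_species(sbml_model, met.id, met.compartment)
        if met.formula:
            sbml_model.getSpecies(met.id).getPlugin("fbc").setChemicalFormula(
                met.formula
            )
    for rxn in model.reactions:
        _add_reaction(
            sbml_model, rxn.id, rxn.stoichiometry, rxn.lower_bound,
            rxn.upper_bound, cache, rxn.name,
        )
    libsbml.writeSBMLToFile(doc, str(path))


def _write_plant_sbml(model: WholePlantModel, path: str | Path) -> None:
    if model.n_cols == 0:
        raise ModelError("refusing to write an empty model")
    doc, sbml_model = _new_document()
    sbml_model.setId("whole_plant")
    seen: set[str] = set()
    cache: dict[float, str] = {}
    for rid in model.row_ids:
        info = model.row_info[rid]
        if info.kind == ROW_TISSUE:
            base_comp = model.base.metabolite(info.species).compartment \
                if model.base.has_metabolite(info.species) else "c"
            comp = f"{base_comp}{SEP}{info.tissue}{SEP}{info.period}"
        elif info.kind == ROW_COMMON_POOL:
            comp = f"CP_{info.pool}{SEP}{info.period}"
        else:
            comp = f"SP{SEP}{info.tissue}"
        _add_compartment(sbml_model, comp, seen)
        _add_species(sbml_model, rid, comp)
    for col in model.columns:
        _add_reaction(sbml_model, col.id, col.stoich, col.lb, col.ub, cache)
    objective_cols = [c for c in model.columns if c.objective != 0.0]
    if objective_cols:
        fbc = sbml_model.getPlugin("fbc")
        obj = fbc.createObjective()
        obj.setId("photon_min")
        obj.setType("minimize")
        fbc.setActiveObjectiveId("photon_min")
        for col in objective_cols:
            fo = obj.createFluxObjective()
            fo.setReaction(col.id)
            fo.setCoefficient(col.objective)
    libsbml.writeSBMLToFile(doc, str(path))


# -- reading an assembled model back ----------------------------------------


def read_plant_sbml(path: str | Path) -> WholePlantModel:
    """Reconstruct a WholePlantModel written by :func:`write_sbml`.

    Provenance is recovered from the id/compartment suffix conventions.  A
    minimal base reconstruction (metabolite compartments and reaction
    membership, default bounds) is rebuilt from the tissue replicas so that
    downstream annotation keeps working; per-replica bounds are of course
    taken from the assembled columns themselves.
    """
    path = str(path)
    doc = libsbml.readSBMLFromFile(path)
    _check_sbml_errors(doc, path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError(f"{path}: no model element")

    rows: list[tuple[str, RowInfo]] = []
    base_mets: dict[str, Metabolite] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid, comp = sp.getId(), sp.getCompartment()
        parts = sid.split(SEP)
        if len(parts) == 3 and parts[1] == "SP":
            rows.append(
                (sid, RowInfo(ROW_STORAGE_POOL, species=parts[0],
                              tissue=parts[2]))
            )
        elif len(parts) == 3 and parts[1].startswith("CP_"):
            rows.append(
                (sid, RowInfo(ROW_COMMON_POOL, species=parts[0],
                              period=parts[2], pool=parts[1][3:]))
            )
        elif len(parts) == 3:
            species, tissue, period = parts
            rows.append(
                (sid, RowInfo(ROW_TISSUE, species=species, tissue=tissue,
                              period=period))
            )
            base_comp = comp.split(SEP)[0] if comp else "c"
            base_mets.setdefault(species, Metabolite(species, compartment=base_comp))
        elif len(parts) == 2 and comp.startswith("SP"):
            # storage row written as {species}__SP_{tissue}-style compartment
            rows.append(
                (sid, RowInfo(ROW_STORAGE_POOL, species=parts[0],
                              tissue=comp.split(SEP)[-1]))
            )
        else:
            raise SBMLReadError(f"{path}: unrecognized species id {sid!r}")

    cols: list[tuple[str, dict, float, float, FluxInfo]] = []
    base_rxns: dict[str, Reaction] = {}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        stoich: dict[str, float] = {}
        for ref, sign in _iter_species_refs(rxn):
            stoich[ref.getSpecies()] = (
                stoich.get(ref.getSpecies(), 0.0) + sign * ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        lb, ub = _reaction_bounds(sbml_model, rxn)
        if lb is None or ub is None:
            lb = -DEFAULT_BOUND if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        parts = rid.split(SEP)
        if parts[0] == "TX" and len(parts) == 6:
            info = FluxInfo(
                kind="transport", species=parts[1], tissue=parts[2],
                pool=parts[3], direction=parts[4], period=parts[5],
            )
        elif parts[0] == "AC" and len(parts) == 4:
            info = FluxInfo(
                kind="accumulation", species=parts[1], tissue=parts[2],
                pool="SP", period=parts[3],
            )
        elif len(parts) == 3:
            base_id, tissue, period = parts
            kind = "exchange" if len(stoich) == 1 else "reaction"
            info = FluxInfo(
                kind=kind, base_reaction=base_id, tissue=tissue, period=period
            )
            if base_id not in base_rxns:
                base_stoich = {
                    m.split(SEP)[0]: c for m, c in stoich.items()
                }
                base_rxns[base_id] = Reaction(
                    base_id, base_stoich, -DEFAULT_BOUND, DEFAULT_BOUND,
                    is_exchange=kind == "exchange",
                )
        else:
            raise SBMLReadError(f"{path}: unrecognized reaction id {rid!r}")
        cols.append((rid, stoich, lb, ub, info))

    objective: dict[str, float] = {}
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            objective[fo.getReaction()] = fo.getCoefficient()

    base = BaseGEM(base_mets.values(), base_rxns.values(), {"source": path})
    model = WholePlantModel(base)
    for rid, info in rows:
        model.add_row(rid, info)
    for rid, stoich, lb, ub, info in cols:
        model.add_column(rid, stoich, lb, ub, info, objective.get(rid, 0.0))
    return model
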