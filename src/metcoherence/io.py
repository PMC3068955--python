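"""Readers and writers for the interchange formats.

All tabular inputs are plain TSV with fixed headers; stoichiometric
models are additionally read/written as an SBML level-3 `fbc` subset
(species, reactions, flux bounds, gene associations, one maximization
objective) via python-libsbml.  Malformed rows are rejected with the
line number and offending field.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable

import libsbml

from .coherence import ExpressionCalls
from .fba import FluxModel, MediumDefinition
from .network import GeneNetwork, Reaction
from .trn import TRN, TRNEdge

__all__ = [
    "read_reaction_table",
    "write_reaction_table",
    "read_currency_list",
    "write_currency_list",
    "read_expression_calls",
    "write_expression_calls",
    "read_trn_table",
    "write_trn_table",
    "write_gene_network",
    "read_flux_model_tsv",
    "write_flux_model_tsv",
    "read_medium",
    "write_medium",
    "read_sbml_model",
    "write_sbml_model",
]

REACTION_HEADER = ["reaction_id", "substrates", "products", "reversible", "genes", "pathways"]
_LOCAL_CURRENCY_COL = "local_currency"


class TableFormatError(ValueError):
    """A TSV row violating the declared format, with its line number."""


def _split_multi(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(part for part in cell.split("|") if part)


def _rows(path: str | Path, expected_prefix: list[str]) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        if header[: len(expected_prefix)] != expected_prefix:
            raise TableFormatError(
                f"{path}: header {header!r} does not start with {expected_prefix!r}"
            )
        return header, [(lineno, row) for lineno, row in enumerate(reader, start=2) if row]


def read_reaction_table(
    path: str | Path,
    declared_metabolites: set[str] | None = None,
) -> list[Reaction]:
    """Parse a reaction TSV.

    Columns: ``reaction_id substrates products reversible genes
    pathways`` with ``|``-separated multi-valued cells; an optional
    trailing ``local_currency`` column lists per-reaction currency
    exceptions.  When ``declared_metabolites`` is given, every
    substrate/product must be in it (line-numbered rejection
    otherwise).
    """
    header, rows = _rows(path, REACTION_HEADER)
    has_local = len(header) > 6 and header[6] == _LOCAL_CURRENCY_COL
    reactions = []
    for lineno, row in rows:
        if len(row) < 5:
            raise TableFormatError(f"{path}:{lineno}: expected >=5 fields, got {len(row)}")
        rid = row[0].strip()
        if not rid:
            raise TableFormatError(f"{path}:{lineno}: empty reaction_id")
        subs = _split_multi(row[1])
        prods = _split_multi(row[2])
        rev_cell = row[3].strip()
        if rev_cell not in {"0", "1"}:
            raise TableFormatError(
                f"{path}:{lineno}: field 'reversible' must be 0 or 1, got {rev_cell!r}"
            )
        genes = _split_multi(row[4])
        pathways = _split_multi(row[5]) if len(row) > 5 else frozenset()
        local = _split_multi(row[6]) if has_local and len(row) > 6 else frozenset()
        if declared_metabolites is not None:
            for side_name, side in (("substrates", subs), ("products", prods)):
                unknown = side - declared_metabolites
                if unknown:
                    raise TableFormatError(
                        f"{path}:{lineno}: unknown metabolite(s) in {side_name}: "
                        + ", ".join(sorted(unknown))
                    )
        reactions.append(
            Reaction(
                id=rid, substrates=subs, products=prods,
                reversible=rev_cell == "1", genes=genes, pathways=pathways,
                local_currency=local,
            )
        )
    return reactions


def write_reaction_table(reactions: Iterable[Reaction], path: str | Path) -> None:
    reactions = list(reactions)
    has_local = any(r.local_currency for r in reactions)
    header = REACTION_HEADER + ([_LOCAL_CURRENCY_COL] if has_local else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(header)
        for r in reactions:
            row = [
                r.id,
                "|".join(sorted(r.substrates)),
                "|".join(sorted(r.products)),
                "1" if r.reversible else "0",
                "|".join(sorted(r.genes)),
                "|".join(sorted(r.pathways)),
            ]
            if has_local:
                row.append("|".join(sorted(r.local_currency)))
            writer.writerow(row)


def read_currency_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_currency_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(ids):
            fh.write(m + "\n")


def read_expression_calls(
    path: str | Path, background: str = "", contrast: str = ""
) -> ExpressionCalls:
    """Parse a call table: ``gene_id significant sign``.

    ``significant`` is 0/1; ``sign`` is -1/1 and may be blank for
    non-significant genes.
    """
    _, rows = _rows(path, ["gene_id", "significant", "sign"])
    calls: dict[str, tuple[bool, int | None]] = {}
    for lineno, row in rows:
        if len(row) < 2:
            raise TableFormatError(f"{path}:{lineno}: expected >=2 fields")
        gene = row[0].strip()
        if gene in calls:
            raise TableFormatError(f"{path}:{lineno}: duplicate gene_id {gene!r}")
        sig_cell = row[1].strip()
        if sig_cell not in {"0", "1"}:
            raise TableFormatError(
                f"{path}:{lineno}: field 'significant' must be 0 or 1, got {sig_cell!r}"
            )
        sig = sig_cell == "1"
        sign_cell = row[2].strip() if len(row) > 2 else ""
        if sig:
            if sign_cell not in {"-1", "1", "+1"}:
                raise TableFormatError(
                    f"{path}:{lineno}: field 'sign' must be -1 or 1 for significant genes"
                )
            sign: int | None = 1 if sign_cell in {"1", "+1"} else -1
        else:
            sign = None
        calls[gene] = (sig, sign)
    return ExpressionCalls(calls=calls, background=background, contrast=contrast)


def write_expression_calls(calls: ExpressionCalls, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "significant", "sign"])
        for gene in sorted(calls.calls):
            sig, sign = calls.calls[gene]
            writer.writerow([gene, "1" if sig else "0", "" if sign is None else str(sign)])


def read_trn_table(path: str | Path) -> TRN:
    """Parse a TRN edge table: ``regulator target effect`` (+, -, +-)."""
    _, rows = _rows(path, ["regulator", "target", "effect"])
    edges = []
    for lineno, row in rows:
        if len(row) < 3:
            raise TableFormatError(f"{path}:{lineno}: expected 3 fields")
        effect = row[2].strip()
        if effect not in {"+", "-", "+-"}:
            raise TableFormatError(
                f"{path}:{lineno}: field 'effect' must be one of + - +-, got {effect!r}"
            )
        edges.append(TRNEdge(regulator=row[0].strip(), target=row[1].strip(), effect=effect))
    return TRN(edges=edges)


def write_trn_table(trn: TRN, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["regulator", "target", "effect"])
        for e in trn.edges:
            writer.writerow([e.regulator, e.target, e.effect])


def write_gene_network(net: GeneNetwork, edge_path: str | Path, node_path: str | Path) -> None:
    """Two-column edge list plus a node list (covers isolated nodes)."""
    with open(edge_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["source", "target"])
        for u, v in sorted(net.edges):
            writer.writerow([u, v])
    with open(node_path, "w") as fh:
        for n in sorted(net.nodes):
            fh.write(n + "\n")


def read_flux_model_tsv(path: str | Path, objective: str = "BIOMASS") -> FluxModel:
    """Parse the TSV model fallback.

    Columns: ``reaction_id metabolite:coef|... lb ub genes``.
    """
    _, rows = _rows(path, ["reaction_id", "stoichiometry", "lb", "ub", "genes"])
    stoich: dict[str, dict[str, float]] = {}
    lbs: dict[str, float] = {}
    ubs: dict[str, float] = {}
    genes: dict[str, frozenset[str]] = {}
    for lineno, row in rows:
        if len(row) < 5:
            raise TableFormatError(f"{path}:{lineno}: expected 5 fields")
        rid = row[0].strip()
        if rid in stoich:
            raise TableFormatError(f"{path}:{lineno}: duplicate reaction_id {rid!r}")
        coeffs: dict[str, float] = {}
        for part in row[1].split("|"):
            part = part.strip()
            if not part:
                continue
            if ":" not in part:
                raise TableFormatError(
                    f"{path}:{lineno}: field 'stoichiometry' entry {part!r} lacks ':'"
                )
            met, _, coef = part.rpartition(":")
            try:
                coeffs[met] = float(coef)
            except ValueError:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric coefficient in {part!r}"
                ) from None
        try:
            lbs[rid] = float(row[2])
            ubs[rid] = float(row[3])
        except ValueError:
            raise TableFormatError(f"{path}:{lineno}: non-numeric bound") from None
        stoich[rid] = coeffs
        genes[rid] = _split_multi(row[4])
    return FluxModel(
        stoichiometry=stoich, lower_bounds=lbs, upper_bounds=ubs,
        objective=objective, genes=genes,
    )


def write_flux_model_tsv(model: FluxModel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["reaction_id", "stoichiometry", "lb", "ub", "genes"])
        for rid in model.reaction_ids:
            coeffs = model.stoichiometry[rid]
            writer.writerow([
                rid,
                "|".join(f"{m}:{coeffs[m]:g}" for m in sorted(coeffs)),
                f"{model.lower_bounds.get(rid, 0.0):g}",
                f"{model.upper_bounds.get(rid, 1e6):g}",
                "|".join(sorted(model.genes.get(rid, frozenset()))),
            ])


def read_medium(path: str | Path) -> MediumDefinition:
    _, rows = _rows(path, ["exchange_id", "uptake_bound"])
    bounds = {}
    for lineno, row in rows:
        try:
            bounds[row[0].strip()] = float(row[1])
        except (ValueError, IndexError):
            raise TableFormatError(f"{path}:{lineno}: malformed medium row") from None
    return MediumDefinition(bounds)


def write_medium(medium: MediumDefinition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["exchange_id", "uptake_bound"])
        for ex in sorted(medium.bounds):
            writer.writerow([ex, f"{medium.bounds[ex]:g}"])


# ---------------------------------------------------------------------------
# SBML (level-3 fbc subset)

_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    sid = _SANITIZE.sub("_", raw)
    return sid if sid and not sid[0].isdigit() else "x" + sid


def write_sbml_model(model: FluxModel, path: str | Path) -> None:
    """Serialize as SBML level 3 with the fbc package (strict)."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId("model")
    mplug = sbml.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sbml.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for m in model.metabolite_ids:
        sp = sbml.createSpecies()
        sp.setId(_sid(m))
        sp.setName(m)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    all_genes = sorted({g for gs in model.genes.values() for g in gs})
    for g in all_genes:
        gp = mplug.createGeneProduct()
        gp.setId(_sid(g))
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in model.reaction_ids:
        rxn = sbml.createReaction()
        rxn.setId(_sid(rid))
        rxn.setName(rid)
        rxn.setFast(False)
        lb = model.lower_bounds.get(rid, 0.0)
        rxn.setReversible(lb < 0)
        for met, coef in sorted(model.stoichiometry[rid].items()):
            ref = rxn.createReactant() if coef < 0 else rxn.createProduct()
            ref.setSpecies(_sid(met))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(lb))
        rplug.setUpperFluxBound(bound_param(model.upper_bounds.get(rid, 1e6)))
        gs = sorted(model.genes.get(rid, frozenset()))
        if gs:
            gpa = rplug.createGeneProductAssociation()
            if len(gs) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(_sid(gs[0]))
            else:
                or_node = gpa.createOr()
                for g in gs:
                    ref = or_node.createGeneProductRef()
                    ref.setGeneProduct(_sid(g))

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid(model.objective))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _collect_gene_refs(assoc) -> set[str]:
    out: set[str] = set()
    if assoc is None:
        return out
    if isinstance(assoc, libsbml.GeneProductRef):
        out.add(assoc.getGeneProduct())
        return out
    for i in range(assoc.getNumAssociations()):
        out |= _collect_gene_refs(assoc.getAssociation(i))
    return out


def read_sbml_model(path: str | Path) -> FluxModel:
    """Parse the SBML subset back into a FluxModel.

    Reads fbc flux bounds and objective when present; falls back to
    kinetic-law LOWER_BOUND/UPPER_BOUND parameters (legacy level-2
    style) and a reaction literally named/id'd like the biomass
    reaction otherwise.  Gene associations are flattened to the union
    of referenced gene products.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise ValueError(f"{path}: not a parsable SBML file")
    sbml = doc.getModel()
    mplug = sbml.getPlugin("fbc")

    gp_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gp_labels[gp.getId()] = gp.getLabel() or gp.getId()

    species_names = {
        sbml.getSpecies(i).getId(): sbml.getSpecies(i).getName() or sbml.getSpecies(i).getId()
        for i in range(sbml.getNumSpecies())
    }

    stoich: dict[str, dict[str, float]] = {}
    lbs: dict[str, float] = {}
    ubs: dict[str, float] = {}
    genes: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i in range(sbml.getNumReactions()):
        rxn = sbml.getReaction(i)
        rid = rxn.getName() or rxn.getId()
        names[rxn.getId()] = rid
        coeffs: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            met = species_names[ref.getSpecies()]
            coeffs[met] = coeffs.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            met = species_names[ref.getSpecies()]
            coeffs[met] = coeffs.get(met, 0.0) + ref.getStoichiometry()
        stoich[rid] = coeffs

        lb, ub = (-1e6 if rxn.getReversible() else 0.0), 1e6
        rplug = rxn.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = sbml.getParameter(rplug.getLowerFluxBound()).getValue()
            ub = sbml.getParameter(rplug.getUpperFluxBound()).getValue()
        elif rxn.isSetKineticLaw():
            kl = rxn.getKineticLaw()
            for k in range(kl.getNumParameters()):
                par = kl.getParameter(k)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
        lbs[rid], ubs[rid] = lb, ub

        gene_ids: set[str] = set()
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gene_ids = _collect_gene_refs(
                rplug.getGeneProductAssociation().getAssociation()
            )
        genes[rid] = frozenset(gp_labels.get(g, g) for g in gene_ids)

    objective = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active.getNumFluxObjectives() > 0:
            objective = names[active.getFluxObjective(0).getReaction()]
    if objective is None:
        candidates = [r for r in stoich if "biomass" in r.lower()]
        if not candidates:
            raise ValueError(f"{path}: no objective declared and no biomass reaction found")
        objective = candidates[0]

    return FluxModel(
        stoichiometry=stoich, lower_bounds=lbs, upper_bounds=ubs,
        objective=objective, genes=genes,
    )
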