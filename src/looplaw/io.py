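"""Reading and writing networks and flux vectors.

The native format is a sectioned TSV file (``[reactions]`` and
``[stoichiometry]`` tables) whose coefficients are fraction strings, so a
round-trip is exact.  SBML Level 3 is supported read-only via python-libsbml.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

from ._rational import to_fraction
from .model import (
    DEFAULT_FLUX_TOLERANCE,
    FluxDistribution,
    StoichiometricNetwork,
    ValidationError,
    classify_reactions,
)

_DEFAULT_BOUND = 1000.0


def _parse_fraction(text: str, where: str) -> Fraction:
    try:
        return Fraction(text)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValidationError(f"{where}: unparseable coefficient {text!r} ({exc})") from None


def read_network(path, format: str | None = None) -> StoichiometricNetwork:
    """Load a network from TSV (native) or SBML, validating as it goes.

    ``format`` is ``"tsv"`` or ``"sbml"``; when omitted it is inferred from
    the extension (``.xml``/``.sbml`` → SBML, anything else → TSV).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "tsv"
    if format == "tsv":
        return read_network_tsv(path)
    if format == "sbml":
        return read_network_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def read_network_tsv(path) -> StoichiometricNetwork:
    """Parse the sectioned TSV network format.

    Sections are headed by ``[reactions]`` and ``[stoichiometry]`` lines; each
    section starts with a tab-separated header row.  The reactions table needs
    ``reaction_id``, ``lower_bound``, ``upper_bound`` and optionally
    ``is_internal`` (0/1); without explicit labels the single-nonzero-column
    heuristic is applied.
    """
    path = Path(path)
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: list[tuple[int, list[str]]] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.strip().startswith("[") and line.strip().endswith("]"):
            name = line.strip()[1:-1].strip().lower()
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise ValidationError(f"{path}:{lineno}: data before any [section] header")
        current.append((lineno, line.split("\t")))
    for required in ("reactions", "stoichiometry"):
        if required not in sections or not sections[required]:
            raise ValidationError(f"{path}: missing [{required}] section")

    # reactions table
    hdr_line, header = sections["reactions"][0]
    cols = {name: i for i, name in enumerate(header)}
    for required in ("reaction_id", "lower_bound", "upper_bound"):
        if required not in cols:
            raise ValidationError(f"{path}:{hdr_line}: reactions table lacks column {required!r}")
    has_labels = "is_internal" in cols
    reaction_ids: list[str] = []
    internal: list[bool] = []
    lbs: list[float] = []
    ubs: list[float] = []
    for lineno, row in sections["reactions"][1:]:
        where = f"{path}:{lineno}"
        if len(row) != len(header):
            raise ValidationError(f"{where}: expected {len(header)} fields, got {len(row)}")
        rid = row[cols["reaction_id"]]
        if rid in reaction_ids:
            raise ValidationError(f"{where}: duplicate reaction {rid!r}")
        reaction_ids.append(rid)
        try:
            lbs.append(float(row[cols["lower_bound"]]))
            ubs.append(float(row[cols["upper_bound"]]))
        except ValueError as exc:
            raise ValidationError(f"{where}: bad bound ({exc})") from None
        if has_labels:
            flag = row[cols["is_internal"]].strip()
            if flag not in ("0", "1"):
                raise ValidationError(f"{where}: is_internal must be 0 or 1, got {flag!r}")
            internal.append(flag == "1")

    # stoichiometry table
    hdr_line, header = sections["stoichiometry"][0]
    cols = {name: i for i, name in enumerate(header)}
    for required in ("metabolite_id", "reaction_id", "coefficient"):
        if required not in cols:
            raise ValidationError(f"{path}:{hdr_line}: stoichiometry table lacks column {required!r}")
    rxn_index = {r: j for j, r in enumerate(reaction_ids)}
    metabolite_ids: list[str] = []
    met_index: dict[str, int] = {}
    entries: dict[tuple[int, int], Fraction] = {}
    seen_reactions: set[str] = set()
    for lineno, row in sections["stoichiometry"][1:]:
        where = f"{path}:{lineno}"
        if len(row) != len(header):
            raise ValidationError(f"{where}: expected {len(header)} fields, got {len(row)}")
        met, rxn = row[cols["metabolite_id"]], row[cols["reaction_id"]]
        if rxn not in rxn_index:
            raise ValidationError(f"{where}: reaction {rxn!r} absent from the reactions table")
        seen_reactions.add(rxn)
        if met not in met_index:
            met_index[met] = len(metabolite_ids)
            metabolite_ids.append(met)
        key = (met_index[met], rxn_index[rxn])
        if key in entries:
            raise ValidationError(f"{where}: duplicate entry for ({met!r}, {rxn!r})")
        entries[key] = _parse_fraction(row[cols["coefficient"]], where)
    dangling = [r for r in reaction_ids if r not in seen_reactions]
    if dangling:
        raise ValidationError(f"{path}: reactions with no stoichiometry entries: {dangling}")

    m, n = len(metabolite_ids), len(reaction_ids)
    stoich = [[Fraction(0)] * n for _ in range(m)]
    for (i, j), coeff in entries.items():
        stoich[i][j] = coeff
    if not has_labels:
        internal = list(classify_reactions(stoich, reaction_ids))
    return StoichiometricNetwork(metabolite_ids, reaction_ids, stoich, internal, lbs, ubs)


def write_network_tsv(network: StoichiometricNetwork, path) -> None:
    """Serialize to the sectioned TSV format (exact fraction strings)."""
    lines = ["[reactions]", "reaction_id\tis_internal\tlower_bound\tupper_bound"]
    for j, rid in enumerate(network.reaction_ids):
        lines.append(
            f"{rid}\t{int(network.internal_mask[j])}\t{network.lower_bounds[j]:g}\t{network.upper_bounds[j]:g}"
        )
    lines += ["", "[stoichiometry]", "metabolite_id\treaction_id\tcoefficient"]
    for i, met in enumerate(network.metabolite_ids):
        for j, rid in enumerate(network.reaction_ids):
            coeff = network.stoich[i][j]
            if coeff != 0:
                lines.append(f"{met}\t{rid}\t{coeff}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_sbml(path) -> StoichiometricNetwork:
    """Minimal read-only SBML import: stoichiometry, bounds, boundary flags.

    Non-boundary species become metabolites.  A reaction touching a
    boundary-condition species, carrying the exchange SBO term (627), or left
    with at most one nonzero coefficient is classified exchange.  Bounds come
    from the fbc plugin when present, else from ``reversible`` with ±1000
    defaults.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValidationError(f"{path}: SBML parse errors: {msgs}")
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"{path}: no SBML model element")

    boundary = set()
    metabolite_ids: list[str] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
        else:
            metabolite_ids.append(sp.getId())
    met_index = {s: i for i, s in enumerate(metabolite_ids)}

    def _bound_value(param_id: str, default: float) -> float:
        p = model.getParameter(param_id) if param_id else None
        return p.getValue() if p is not None else default

    reaction_ids, internal, lbs, ubs = [], [], [], []
    n_rxns = model.getNumReactions()
    stoich = [[Fraction(0)] * n_rxns for _ in metabolite_ids]
    for j in range(n_rxns):
        rxn = model.getReaction(j)
        reaction_ids.append(rxn.getId())
        touches_boundary = False
        for ref, s in [(rxn.getReactant(k), -1) for k in range(rxn.getNumReactants())] + [
            (rxn.getProduct(k), +1) for k in range(rxn.getNumProducts())
        ]:
            sp = ref.getSpecies()
            if sp in boundary:
                touches_boundary = True
                continue
            coeff = to_fraction(ref.getStoichiometry()) * s
            stoich[met_index[sp]][j] += coeff
        fbc = rxn.getPlugin("fbc")
        if fbc is not None and (fbc.getLowerFluxBound() or fbc.getUpperFluxBound()):
            lbs.append(_bound_value(fbc.getLowerFluxBound(), -_DEFAULT_BOUND))
            ubs.append(_bound_value(fbc.getUpperFluxBound(), _DEFAULT_BOUND))
        else:
            lbs.append(-_DEFAULT_BOUND if rxn.getReversible() else 0.0)
            ubs.append(_DEFAULT_BOUND)
        nnz = sum(1 for i in range(len(metabolite_ids)) if stoich[i][j] != 0)
        is_exchange = touches_boundary or rxn.getSBOTerm() == 627 or nnz <= 1
        internal.append(not is_exchange)
    return StoichiometricNetwork(metabolite_ids, reaction_ids, stoich, internal, lbs, ubs)


def read_flux_tsv(
    path, network: StoichiometricNetwork, tolerance: float = DEFAULT_FLUX_TOLERANCE
) -> FluxDistribution:
    """Two-column TSV (reaction_id, value), header optional; keys must cover the network."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
        rid, val = parts
        if lineno == 1 and rid.lower() in ("reaction_id", "reaction"):
            continue
        try:
            values[rid] = float(val)
        except ValueError:
            if lineno == 1:
                continue  # tolerate an arbitrary header row
            raise ValidationError(f"{path}:{lineno}: bad flux value {val!r}") from None
    missing = [r for r in network.reaction_ids if r not in values]
    if missing:
        raise ValidationError(f"{path}: flux values missing for reactions: {missing}")
    return FluxDistribution.from_dict(network, values, tolerance)
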