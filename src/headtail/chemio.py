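"""CSV input/output, reaction-SMILES parsing and monomer selection.

Monomer selection follows the similarity protocol of the pipeline: every
reactant is fingerprinted with RDKit's path-based topological fingerprint
and compared with the (largest) product by Tanimoto similarity; the most
product-like reactant is taken to be the monomer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields

from rdkit import Chem
from rdkit.DataStructs import TanimotoSimilarity as _rdkit_tanimoto

from .errors import ConfigurationError, SmilesParseError

__all__ = [
    "InputRecord", "ReactionParts", "MonomerSelection", "ResultRow",
    "read_input_csv", "parse_reaction_smiles", "topological_fingerprint",
    "tanimoto", "select_monomer", "write_results_csv", "read_results_csv",
    "strip_atom_maps", "canonical_mol",
]

NAME_COLUMN_ALIASES = ("polymer_name", "name", "polymer")
SMILES_COLUMN_ALIASES = ("smiles", "reaction", "reaction_smiles")


@dataclass(frozen=True)
class InputRecord:
    polymer_name: str
    raw_smiles: str
    record_kind: str            # "monomer" | "reaction"
    is_valid: bool = True
    error: str = ""


@dataclass(frozen=True)
class ReactionParts:
    reactants: tuple[str, ...]
    agents: tuple[str, ...]
    products: tuple[str, ...]


@dataclass(frozen=True)
class MonomerSelection:
    monomer_smiles: str
    # order-preserving (reactant SMILES, similarity) pairs; duplicates kept
    similarity_by_reactant: tuple[tuple[str, float], ...]


@dataclass
class ResultRow:
    """One output-CSV row; all fields are strings for lossless round-trips."""

    polymer_name: str = ""
    input_smiles: str = ""
    reaction_mapped: str = ""
    reaction_unmapped: str = ""
    monomer_smiles: str = ""
    polymer_class: str = ""
    mechanism: str = ""
    vinyl_subcategory: str = ""
    tagged_smiles: str = ""
    head_atom_index: str = ""
    tail_atom_index: str = ""
    status: str = "ok"
    message: str = ""


RESULT_COLUMNS = tuple(f.name for f in fields(ResultRow))


def canonical_mol(smiles: str) -> tuple[str, Chem.Mol]:
    """Parse a single-component SMILES and return (canonical SMILES, mol)
    with the mol's atom order equal to the canonical SMILES atom order.

    All atom indices downstream (matches, reactivity, head/tail) refer to
    this order.
    """
    mol0 = Chem.MolFromSmiles(smiles)
    if mol0 is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    can = Chem.MolToSmiles(mol0)
    mol = Chem.MolFromSmiles(can)
    return can, mol


def strip_atom_maps(smiles: str) -> str:
    """Remove atom-map numbers from a (possibly reaction) SMILES string."""
    def _strip_one(part: str) -> str:
        out = []
        for comp in part.split("."):
            m = Chem.MolFromSmiles(comp)
            if m is None:
                raise SmilesParseError(f"invalid SMILES component: {comp!r}")
            for a in m.GetAtoms():
                a.SetAtomMapNum(0)
            out.append(Chem.MolToSmiles(m))
        return ".".join(out)

    if ">" in smiles:
        return ">".join(_strip_one(p) if p else "" for p in smiles.split(">"))
    return _strip_one(smiles)


def read_input_csv(path, name_aliases=NAME_COLUMN_ALIASES,
                   smiles_aliases=SMILES_COLUMN_ALIASES) -> list[InputRecord]:
    """Read the pipeline's input CSV into records, preserving row order.

    Unparseable SMILES are flagged invalid on the record, never dropped.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file, expected a header")
        lower = {c.lower().strip(): c for c in reader.fieldnames}
        name_col = next((lower[a] for a in name_aliases if a in lower), None)
        smi_col = next((lower[a] for a in smiles_aliases if a in lower), None)
        if name_col is None or smi_col is None:
            raise ConfigurationError(
                f"{path}: need a polymer-name column (one of {name_aliases}) "
                f"and a SMILES column (one of {smiles_aliases}); "
                f"found {tuple(reader.fieldnames)}")
        records = []
        for row in reader:
            name = (row.get(name_col) or "").strip()
            smi = (row.get(smi_col) or "").strip()
            kind = "reaction" if ">>" in smi or smi.count(">") == 2 else "monomer"
            valid, err = True, ""
            try:
                if kind == "reaction":
                    parse_reaction_smiles(smi)
                else:
                    for comp in smi.split("."):
                        if Chem.MolFromSmiles(comp) is None:
                            raise SmilesParseError(f"invalid component {comp!r}")
            except (SmilesParseError, ValueError) as exc:
                valid, err = False, str(exc)
            records.append(InputRecord(name, smi, kind, valid, err))
    return records


def parse_reaction_smiles(s: str) -> ReactionParts:
    """Split ``reactants>agents>products`` (or ``reactants>>products``)."""
    parts = s.split(">")
    if len(parts) != 3:
        raise SmilesParseError(
            f"reaction SMILES must have 3 '>'-separated fields, got "
            f"{len(parts)} in {s!r}")
    names = ("reactant", "agent", "product")
    comps: list[tuple[str, ...]] = []
    for fieldname, part in zip(names, parts):
        items = tuple(c for c in part.split(".") if c)
        for c in items:
            if Chem.MolFromSmiles(c) is None:
                raise SmilesParseError(f"invalid {fieldname} SMILES: {c!r}")
        comps.append(items)
    reactants, agents, products = comps
    if not reactants:
        raise SmilesParseError(f"empty reactant field in {s!r}")
    if not products:
        raise SmilesParseError(f"empty product field in {s!r}")
    return ReactionParts(reactants, agents, products)


def topological_fingerprint(smiles: str):
    """RDKit path-based topological fingerprint (atom maps ignored)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.RDKFingerprint(mol)


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a&b|/|a|b|; defined as 0.0 when both are empty."""
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(_rdkit_tanimoto(a, b))


def select_monomer(parts: ReactionParts) -> MonomerSelection:
    """Pick the reactant most similar to the (largest) product.

    Ties keep the first-listed reactant; multi-product reactions compare
    against the product with the most heavy atoms.
    """
    if not parts.reactants or not parts.products:
        raise ValueError("select_monomer needs >=1 reactant and >=1 product")
    prod_mols = [(Chem.MolFromSmiles(p), p) for p in parts.products]
    prod_mols = [(m, p) for m, p in prod_mols if m is not None]
    if not prod_mols:
        raise SmilesParseError("no parseable product")
    target = max(prod_mols, key=lambda mp: mp[0].GetNumHeavyAtoms())[1]
    fp_prod = topological_fingerprint(target)
    sims = []
    for r in parts.reactants:
        sims.append((r, tanimoto(topological_fingerprint(r), fp_prod)))
    if not sims:
        raise SmilesParseError("no parseable reactant")
    best = max(range(len(sims)), key=lambda i: sims[i][1])
    # max() keeps the first occurrence on ties
    return MonomerSelection(sims[best][0], tuple(sims))


def write_results_csv(rows: list[ResultRow], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for row in rows:
            writer.writerow([getattr(row, c) for c in RESULT_COLUMNS])


def read_results_csv(path) -> list[ResultRow]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [ResultRow(**{k: row.get(k, "") for k in RESULT_COLUMNS})
                for row in reader]
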