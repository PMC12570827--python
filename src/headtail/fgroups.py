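"""Functional-group SMARTS library and polymer-class candidate rules.

Five classes are recognized: polyvinyl, polyamide, polyester, polyether
and polyurethane.  The default rules deliberately reproduce the known
behavior of the reference protocol, including its treatment of lactones:
a cyclic ester carries no free carboxylic acid, so by default it
satisfies only the cyclic-ether rule and lands in the polyether class.
``fix_lactones=True`` opts into an explicit lactone→polyester rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml
from rdkit import Chem

from .chemio import canonical_mol
from .errors import ConfigurationError

__all__ = [
    "FunctionalGroupPattern", "FunctionalGroupMatch", "ClassCandidate",
    "load_pattern_library", "match_groups", "candidate_classes",
    "POLYMER_CLASSES", "LACTONE_SMARTS", "NUCLEOPHILIC_PATTERNS_BY_CLASS",
]

POLYMER_CLASSES = ("polyvinyl", "polyamide", "polyester", "polyurethane",
                   "polyether")

LACTONE_SMARTS = "[CX3](=O)[OX2;R]"   # opt-in corrected polyester rule


@dataclass(frozen=True)
class FunctionalGroupPattern:
    name: str
    smarts: str
    role: str                   # nucleophile | electrophile | structural

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ConfigurationError(
                f"SMARTS for pattern {self.name!r} does not compile: "
                f"{self.smarts!r}")
        return q


@dataclass(frozen=True)
class FunctionalGroupMatch:
    pattern_name: str
    atom_indices: tuple[int, ...]   # canonical atom order of the component
    component_index: int = 0


@dataclass(frozen=True)
class ClassCandidate:
    polymer_class: str
    supporting_matches: tuple[FunctionalGroupMatch, ...]
    requires_two_components: bool = False


_DEFAULT_PATTERNS = (
    FunctionalGroupPattern("alkene", "[CX3]=[CX3]", "nucleophile"),
    FunctionalGroupPattern("alkyne", "[CX2]#[CX2]", "nucleophile"),
    FunctionalGroupPattern("primary_amine", "[NX3;H2][#6]", "nucleophile"),
    FunctionalGroupPattern("carboxylic_acid", "[CX3](=O)[OX2H1]", "electrophile"),
    FunctionalGroupPattern("acyl_halide", "[CX3](=O)[F,Cl,Br,I]", "electrophile"),
    FunctionalGroupPattern("secondary_amide", "[NX3;H1][CX3]=O", "nucleophile"),
    FunctionalGroupPattern("heterocycle", "[O,N;R]", "structural"),
    FunctionalGroupPattern("aliphatic_alcohol", "[CX4][OX2H]", "nucleophile"),
    FunctionalGroupPattern("ether", "[OX2]([#6])[#6]", "nucleophile"),
    FunctionalGroupPattern("hydroxyl", "[OX2H]", "nucleophile"),
    FunctionalGroupPattern("isocyanate", "[NX2]=[CX2]=[OX1]", "electrophile"),
)

# patterns whose match hosts the head (nucleophilic) atom, per class
NUCLEOPHILIC_PATTERNS_BY_CLASS = {
    "polyvinyl": ("alkene", "alkyne"),
    "polyamide": ("primary_amine", "secondary_amide"),
    "polyester": ("aliphatic_alcohol", "heterocycle", "lactone"),
    "polyether": ("ether",),
    "polyurethane": ("hydroxyl",),
}


def load_pattern_library(config=None) -> list[FunctionalGroupPattern]:
    """Return the default 11-pattern library, optionally overridden.

    The override file (YAML or JSON) holds a list of
    ``{name, smarts, role}`` mappings; entries replace same-named defaults
    or are appended.  Every SMARTS must compile.
    """
    patterns = list(_DEFAULT_PATTERNS)
    if config is not None:
        text = Path(config).read_text(encoding="utf-8")
        try:
            entries = json.loads(text)
        except json.JSONDecodeError:
            entries = yaml.safe_load(text)
        if not isinstance(entries, list):
            raise ConfigurationError(
                f"{config}: expected a list of {{name, smarts, role}} entries")
        for e in entries:
            try:
                pat = FunctionalGroupPattern(e["name"], e["smarts"],
                                             e.get("role", "structural"))
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(
                    f"{config}: bad pattern entry {e!r}") from exc
            pat.query()    # validates the SMARTS
            names = [p.name for p in patterns]
            if pat.name in names:
                patterns[names.index(pat.name)] = pat
            else:
                patterns.append(pat)
    for p in patterns:
        p.query()
    return patterns


def match_groups(component_smiles: str,
                 patterns: list[FunctionalGroupPattern] | None = None,
                 component_index: int = 0) -> list[FunctionalGroupMatch]:
    """All functional-group hits on one component, in canonical atom order.

    Hits are deduplicated by (pattern, atom set) so symmetric SMARTS do
    not double-report.
    """
    if patterns is None:
        patterns = list(_DEFAULT_PATTERNS)
    _, mol = canonical_mol(component_smiles)
    out: list[FunctionalGroupMatch] = []
    for pat in patterns:
        seen = set()
        for hit in mol.GetSubstructMatches(pat.query(), uniquify=True):
            key = frozenset(hit)
            if key in seen:
                continue
            seen.add(key)
            out.append(FunctionalGroupMatch(pat.name, tuple(hit),
                                            component_index))
    return out


def _names(matches) -> set[str]:
    return {m.pattern_name for m in matches}


def _of(matches, name):
    return [m for m in matches if m.pattern_name == name]


def candidate_classes(matches_per_component: list[list[FunctionalGroupMatch]],
                      component_mols: list[Chem.Mol],
                      fix_lactones: bool = False) -> list[ClassCandidate]:
    """Apply the class-rule table to per-component match lists.

    Rules (evaluated over all components together unless noted):
      polyvinyl    <- alkene or alkyne
      polyamide    <- (primary amine & carboxylic acid)
                      or (primary amine & acyl halide)
                      or (secondary amide whose N sits in a ring)
      polyester    <- (aliphatic alcohol & carboxylic acid)
                      or (ring heteroatom & carboxylic acid)
                      [or, with fix_lactones, a lactone C(=O)O-in-ring]
      polyether    <- ether whose oxygen sits in a ring
      polyurethane <- hydroxyl on one component & isocyanate on another
    An empty list (no class licensed) is a valid outcome.
    """
    all_matches = [m for comp in matches_per_component for m in comp]
    names = _names(all_matches)
    out: list[ClassCandidate] = []

    vinyl = _of(all_matches, "alkene") + _of(all_matches, "alkyne")
    if vinyl:
        out.append(ClassCandidate("polyvinyl", tuple(vinyl)))

    amide_support: list[FunctionalGroupMatch] = []
    if "primary_amine" in names and "carboxylic_acid" in names:
        amide_support = _of(all_matches, "primary_amine") + \
            _of(all_matches, "carboxylic_acid")
    elif "primary_amine" in names and "acyl_halide" in names:
        amide_support = _of(all_matches, "primary_amine") + \
            _of(all_matches, "acyl_halide")
    else:
        for m in _of(all_matches, "secondary_amide"):
            n_atom = m.atom_indices[0]
            if component_mols[m.component_index].GetAtomWithIdx(n_atom).IsInRing():
                amide_support.append(m)
    if amide_support:
        out.append(ClassCandidate("polyamide", tuple(amide_support)))

    ester_support: list[FunctionalGroupMatch] = []
    if "aliphatic_alcohol" in names and "carboxylic_acid" in names:
        ester_support = _of(all_matches, "aliphatic_alcohol") + \
            _of(all_matches, "carboxylic_acid")
    elif "heterocycle" in names and "carboxylic_acid" in names:
        ester_support = _of(all_matches, "heterocycle") + \
            _of(all_matches, "carboxylic_acid")
    if fix_lactones and not ester_support:
        lactone_q = Chem.MolFromSmarts(LACTONE_SMARTS)
        for ci, mol in enumerate(component_mols):
            for hit in mol.GetSubstructMatches(lactone_q, uniquify=True):
                ester_support.append(
                    FunctionalGroupMatch("lactone", tuple(hit), ci))
    if ester_support:
        out.append(ClassCandidate("polyester", tuple(ester_support)))

    ure_support: list[FunctionalGroupMatch] = []
    comps_with_oh = {m.component_index
                     for comp in matches_per_component
                     for m in comp if m.pattern_name == "hydroxyl"}
    comps_with_nco = {m.component_index
                      for comp in matches_per_component
                      for m in comp if m.pattern_name == "isocyanate"}
    if comps_with_oh and comps_with_nco and comps_with_oh != comps_with_nco:
        ure_support = [m for m in all_matches
                       if (m.pattern_name == "hydroxyl"
                           and m.component_index in comps_with_oh - comps_with_nco)
                       or (m.pattern_name == "isocyanate")]
        out.append(ClassCandidate("polyurethane", tuple(ure_support),
                                  requires_two_components=True))

    ether_support = []
    for m in _of(all_matches, "ether"):
        o_atom = m.atom_indices[0]
        if component_mols[m.component_index].GetAtomWithIdx(o_atom).IsInRing():
            ether_support.append(m)
    if ether_support:
        out.append(ClassCandidate("polyether", tuple(ether_support)))

    # deterministic class order (also the cross-class tie-break priority)
    out.sort(key=lambda c: POLYMER_CLASSES.index(c.polymer_class))
    return out
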