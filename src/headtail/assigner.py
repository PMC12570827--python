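"""Class resolution by nucleophilicity, mechanism table, vinyl subcategory.

When several polymer classes are licensed by the functional groups, the
class whose nucleophilic group hosts the largest atomic nucleophilicity
index R_X wins; with one candidate the quantum step is skipped entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import yaml

from .chemio import tanimoto, topological_fingerprint
from .errors import ConfigurationError
from .fgroups import (ClassCandidate, FunctionalGroupMatch,
                      NUCLEOPHILIC_PATTERNS_BY_CLASS, POLYMER_CLASSES)
from .qchem import ReactivityProfile

__all__ = [
    "ClassAssignment", "MechanismAssignment", "resolve_class",
    "assign_mechanism", "vinyl_subcategory", "DEFAULT_INITIATORS",
    "load_initiator_table",
]

# ProfileGetter maps a component index to that component's ReactivityProfile
ProfileGetter = Callable[[int], ReactivityProfile]

MECHANISMS = ("polycondensation", "polyaddition", "ring_opening")

# canonical textbook initiators per polyaddition subcategory
DEFAULT_INITIATORS: dict[str, tuple[str, ...]] = {
    "radical": (
        "O=C(OOC(=O)c1ccccc1)c1ccccc1",          # benzoyl peroxide
        "CC(C)(C#N)/N=N/C(C)(C)C#N",             # AIBN
        "[K+].[K+].[O-]S(=O)(=O)OOS(=O)(=O)[O-]",  # potassium persulfate
    ),
    "anionic": (
        "[Li]CCCC",                              # n-butyllithium
        "[Na+].[NH2-]",                          # sodium amide
    ),
    "cationic": (
        "FB(F)F",                                # boron trifluoride
        "OS(=O)(=O)O",                           # sulfuric acid
        "Cl[Al](Cl)Cl",                          # aluminum trichloride
    ),
}


@dataclass(frozen=True)
class ClassAssignment:
    polymer_class: str
    winning_match: FunctionalGroupMatch
    candidate: ClassCandidate
    # all candidates' supporting matches stay reachable through `candidate`


@dataclass(frozen=True)
class MechanismAssignment:
    mechanism: str
    vinyl_subcategory: str = "unspecified"


def _nucleophilic_matches(candidate: ClassCandidate) -> list[FunctionalGroupMatch]:
    wanted = NUCLEOPHILIC_PATTERNS_BY_CLASS[candidate.polymer_class]
    return [m for m in candidate.supporting_matches if m.pattern_name in wanted]


def _heavy_max_r(match: FunctionalGroupMatch, profile: ReactivityProfile) -> float:
    vals = [profile.nucleophilicity[i] for i in match.atom_indices
            if profile.atom_symbols[i] != "H"]
    if not vals:
        raise RuntimeError(
            f"match {match.pattern_name} has no heavy atom with a computed R_X")
    return float(max(vals))


def resolve_class(candidates: list[ClassCandidate],
                  profile_getter: ProfileGetter) -> ClassAssignment | None:
    """Pick the final class (and its nucleophilic match) among candidates.

    With a single candidate owning a single nucleophilic match the
    profile getter is never called; otherwise each candidate is scored by
    the maximum R_X over the heavy atoms of its nucleophilic matches and
    the best-scoring class wins.  Exact score ties fall back to the fixed
    priority polyvinyl > polyamide > polyester > polyurethane > polyether.
    Returns None for an empty candidate list (row status "unclassified").
    """
    if not candidates:
        return None

    def _winning_match(cand: ClassCandidate,
                       lazy: bool = False) -> FunctionalGroupMatch:
        nucs = _nucleophilic_matches(cand)
        if not nucs:
            # electrophile-only support should not occur under the rule table
            return cand.supporting_matches[0]
        if len(nucs) == 1 or lazy:
            # with one licensed class the quantum step is deferred to head
            # selection; the first match is a deterministic placeholder
            return min(nucs, key=lambda m: (m.component_index,
                                            min(m.atom_indices)))
        return max(nucs, key=lambda m: (_heavy_max_r(m, profile_getter(m.component_index)),
                                        -min(m.atom_indices)))

    if len(candidates) == 1:
        cand = candidates[0]
        return ClassAssignment(cand.polymer_class,
                               _winning_match(cand, lazy=True), cand)

    def _score(cand: ClassCandidate) -> float:
        nucs = _nucleophilic_matches(cand)
        if not nucs:
            return float("-inf")
        return max(_heavy_max_r(m, profile_getter(m.component_index))
                   for m in nucs)

    scored = [(_score(c), -POLYMER_CLASSES.index(c.polymer_class), c)
              for c in candidates]
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    best = scored[0][2]
    return ClassAssignment(best.polymer_class, _winning_match(best), best)


def assign_mechanism(assignment: ClassAssignment,
                     component_mols) -> MechanismAssignment:
    """Fixed class→mechanism table.

    Polyester splits on ring membership of the winning match: a lactone
    route polymerizes by ring opening, the diol/diacid route by
    condensation.
    """
    cls = assignment.polymer_class
    if cls == "polyvinyl":
        return MechanismAssignment("polyaddition")
    if cls in ("polyamide", "polyurethane"):
        return MechanismAssignment("polycondensation")
    if cls == "polyether":
        return MechanismAssignment("ring_opening")
    if cls == "polyester":
        mol = component_mols[assignment.winning_match.component_index]
        in_ring = any(mol.GetAtomWithIdx(i).IsInRing()
                      for i in assignment.winning_match.atom_indices)
        return MechanismAssignment("ring_opening" if in_ring
                                   else "polycondensation")
    raise ValueError(f"unknown polymer class {cls!r}")


def load_initiator_table(config=None) -> dict[str, tuple[str, ...]]:
    """Default initiator table, or a YAML/JSON override mapping
    ``{radical|anionic|cationic: [SMILES, ...]}``."""
    if config is None:
        return dict(DEFAULT_INITIATORS)
    text = Path(config).read_text(encoding="utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{config}: expected a mapping of "
                                 "subcategory -> list of SMILES")
    out = {}
    for k, v in data.items():
        if k not in ("radical", "anionic", "cationic"):
            raise ConfigurationError(f"{config}: unknown subcategory {k!r}")
        out[k] = tuple(v)
    return out


def vinyl_subcategory(reactants: list[str],
                      initiator_table: dict[str, tuple[str, ...]] | None = None
                      ) -> str:
    """Identify the polyaddition subcategory from an initiator present
    among the reactants.

    Assignment requires an exact fingerprint match (Tanimoto == 1.0);
    the first hit in table order wins.  Returns "unspecified" when no
    listed initiator is present.
    """
    table = initiator_table if initiator_table is not None else DEFAULT_INITIATORS
    fps = []
    for r in reactants:
        try:
            fps.append(topological_fingerprint(r))
        except Exception:
            continue
    for subcat, initiators in table.items():
        for ini in initiators:
            fp_ini = topological_fingerprint(ini)
            for fp_r in fps:
                if tanimoto(fp_r, fp_ini) == 1.0:
                    return subcat
    return "unspecified"
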