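"""Head/tail selection, graph-based ring opening and repeat-unit tagging.

All molecular edits are performed on the graph (RDKit ``RWMol``), never on
the SMILES string: bonds are deleted or reduced in order, leaving groups
are removed as atoms, and the wildcard attachment points ``[*:1]``/``[*:2]``
are attached as real graph nodes.  Every emitted repeat unit must pass
full valence sanitization; an invalid structure is reported as such,
never returned silently.

Tag placement convention: ``[*:1]`` on the head (nucleophilic) atom for
addition and condensation routes; for ring-opened units the heteroatom
end carries ``[*:2]`` and the carbon end ``[*:1]`` (the distinction is
cosmetic — validation collapses both tokens).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import RWMol

from .assigner import ClassAssignment, ProfileGetter
from .fgroups import FunctionalGroupMatch
from .qchem import ReactivityProfile

__all__ = [
    "HeadTailAssignment", "TaggedMonomer", "AssemblyResult",
    "select_head_atom", "select_tail_atom", "open_ring",
    "apply_condensation_edits", "tag_monomer", "assemble_repeat_unit",
]

_HEAD_PROP = "_ht_role"   # atom bookkeeping across index-shifting edits


@dataclass(frozen=True)
class HeadTailAssignment:
    component_index: int
    head_atom: int
    tail_atom: int


@dataclass(frozen=True)
class TaggedMonomer:
    tagged_smiles: str
    canonical_form: str
    is_valid: bool
    message: str = ""


@dataclass
class AssemblyResult:
    status: str = "ok"                       # ok | tail-unassigned | edit-failed | unsupported-topology
    message: str = ""
    tagged: list[TaggedMonomer] = field(default_factory=list)
    head_tail: list[HeadTailAssignment] = field(default_factory=list)

    @property
    def tagged_smiles(self) -> str:
        return ".".join(t.tagged_smiles for t in self.tagged)


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)


def _is_acyl_carbon(mol: Chem.Mol, idx: int) -> bool:
    a = mol.GetAtomWithIdx(idx)
    if a.GetSymbol() != "C":
        return False
    for b in a.GetBonds():
        other = b.GetOtherAtom(a)
        if b.GetBondType() == Chem.BondType.DOUBLE and other.GetSymbol() == "O":
            return True
    return False


def _ring_route(assignment: ClassAssignment, mol: Chem.Mol) -> bool:
    if assignment.polymer_class in ("polyvinyl", "polyurethane"):
        return False
    return any(mol.GetAtomWithIdx(i).IsInRing()
               for i in assignment.winning_match.atom_indices)


def _eligible_head_atoms(assignment: ClassAssignment, mol: Chem.Mol) -> list[int]:
    candidates = [i for i in assignment.winning_match.atom_indices
                  if mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
    if _ring_route(assignment, mol):
        ring_only = [i for i in candidates if mol.GetAtomWithIdx(i).IsInRing()]
        candidates = ring_only or candidates
    return candidates


def select_head_atom(assignment: ClassAssignment,
                     profile: ReactivityProfile,
                     mol: Chem.Mol) -> int:
    """Head = heavy atom of the winning nucleophilic match with maximal
    R_X; ties break to the lower canonical index.

    For ring-opening routes only the match atoms inside the ring are
    eligible (exocyclic atoms of the match, e.g. a lactam's carbonyl
    oxygen, cannot be polymerization points of the ring).
    """
    candidates = _eligible_head_atoms(assignment, mol)
    if not candidates:
        raise RuntimeError("winning match has no heavy atom with computed R_X")
    return min(candidates, key=lambda i: (-profile.nucleophilicity[i], i))


def _refine_winning_match(assignment: ClassAssignment,
                          profile_getter: ProfileGetter) -> ClassAssignment:
    """When the winning class owns several nucleophilic matches (e.g. the
    two alkenes of a diene), pick the one hosting the most nucleophilic
    heavy atom.  Part of head selection, so quantum use here does not
    violate the lazy-classification contract."""
    from .assigner import _heavy_max_r, _nucleophilic_matches
    from dataclasses import replace as _dc_replace

    nucs = _nucleophilic_matches(assignment.candidate)
    if len(nucs) <= 1 or assignment.winning_match not in nucs:
        return assignment
    best = max(nucs, key=lambda m: (_heavy_max_r(m, profile_getter(m.component_index)),
                                    -min(m.atom_indices)))
    if best == assignment.winning_match:
        return assignment
    return _dc_replace(assignment, winning_match=best)


def _lazy_head(assignment: ClassAssignment, mol: Chem.Mol, comp_idx: int,
               profile_getter: ProfileGetter) -> int:
    """Skip the quantum profile entirely when only one atom is eligible."""
    candidates = _eligible_head_atoms(assignment, mol)
    if len(candidates) == 1:
        return candidates[0]
    return select_head_atom(assignment, profile_getter(comp_idx), mol)


def select_tail_atom(assignment: ClassAssignment,
                     matches: list[FunctionalGroupMatch],
                     head: int) -> int | None:
    """Tail for the non-ring routes.

    polyvinyl: the partner atom of the reacting multiple bond.
    condensation: the acyl carbon of the carboxylic acid / acyl halide
    (preferring an electrophilic match that does not contain the head).
    Returns None when no electrophilic group exists ("tail-unassigned").
    """
    if assignment.polymer_class == "polyvinyl":
        pair = [i for i in assignment.winning_match.atom_indices if i != head]
        return pair[0] if pair else None
    elec = [m for m in matches
            if m.pattern_name in ("carboxylic_acid", "acyl_halide")
            and m.component_index == assignment.winning_match.component_index]
    elec = ([m for m in elec if head not in m.atom_indices] or elec)
    if not elec:
        return None
    return min(m.atom_indices[0] for m in elec[:1])


def open_ring(mol: Chem.Mol, head: int, polymer_class: str
              ) -> tuple[RWMol | None, int | None, str]:
    """Delete exactly one ring bond incident to ``head``.

    If a ring neighbor of the head is an acyl carbon (lactone/lactam) the
    head–acyl bond is broken; otherwise the bond on the less-substituted
    side (fewer heavy neighbors; ties to the lower index).  No atoms are
    added or removed.  Returns (edited mol, tail atom, status message);
    a head outside any ring is a no-op with a warning status, a fused or
    bridged head is refused.
    """
    atom = mol.GetAtomWithIdx(head)
    if not atom.IsInRing():
        return RWMol(mol), None, "head-not-in-ring"
    rings = [r for r in mol.GetRingInfo().AtomRings() if head in r]
    if len(rings) > 1:
        return None, None, "unsupported-topology"
    ring = set(rings[0])
    nbrs = [n.GetIdx() for n in atom.GetNeighbors()
            if n.GetIdx() in ring
            and mol.GetBondBetweenAtoms(head, n.GetIdx()).IsInRing()]
    acyl = sorted(i for i in nbrs if _is_acyl_carbon(mol, i))
    if acyl:
        tail = acyl[0]
    else:
        tail = min(nbrs, key=lambda i: (_heavy_degree(mol.GetAtomWithIdx(i)), i))
    rw = RWMol(mol)
    rw.RemoveBond(head, tail)
    return rw, tail, ""


def apply_condensation_edits(mol: Chem.Mol, head: int, tail: int,
                             matches: list[FunctionalGroupMatch]
                             ) -> tuple[RWMol | None, str]:
    """Delete the leaving hydroxyl/halide at the tail acyl carbon.

    The head heteroatom loses one hydrogen implicitly when the attachment
    point is bonded later.  Atom bookkeeping survives the index shift of
    the removal via atom properties.
    """
    leaving = None
    for m in matches:
        if m.pattern_name in ("carboxylic_acid", "acyl_halide") \
                and m.atom_indices[0] == tail:
            leaving = m.atom_indices[2]
            break
    if leaving is None:
        return None, "edit-failed: tail carbon lacks a leaving OH/halide"
    rw = RWMol(mol)
    rw.GetAtomWithIdx(head).SetIntProp(_HEAD_PROP, 1)
    rw.GetAtomWithIdx(tail).SetIntProp(_HEAD_PROP, 2)
    rw.RemoveAtom(leaving)
    return rw, ""


def _find_marked(rw: RWMol) -> dict[int, int]:
    out = {}
    for a in rw.GetAtoms():
        if a.HasProp(_HEAD_PROP):
            out[a.GetIntProp(_HEAD_PROP)] = a.GetIdx()
            a.ClearProp(_HEAD_PROP)
    return out


def tag_monomer(rw: RWMol, head: int, tail: int,
                head_label: int = 1) -> TaggedMonomer:
    """Attach ``[*:head_label]`` to the head and the partner token to the
    tail by single bonds, sanitize, and canonicalize.

    A valence failure is reported via ``is_valid=False`` with the RDKit
    diagnostic, never as a silently broken string.
    """
    tail_label = 3 - head_label
    for idx, label in ((head, head_label), (tail, tail_label)):
        star = Chem.Atom(0)
        star.SetAtomMapNum(label)
        new_idx = rw.AddAtom(star)
        rw.AddBond(idx, new_idx, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        return TaggedMonomer(Chem.MolToSmiles(mol, canonical=False)
                             if mol.GetNumAtoms() else "", "", False,
                             f"sanitization failed: {exc}")
    smi = Chem.MolToSmiles(mol)
    return TaggedMonomer(smi, smi, True)


def _profile_rank(profile: ReactivityProfile, atoms: list[int]) -> list[int]:
    return sorted(atoms, key=lambda i: (-profile.nucleophilicity[i], i))


def _tag_sites(mol: Chem.Mol, site1: int, site2: int,
               pre_edit=None) -> TaggedMonomer:
    rw = RWMol(mol)
    if pre_edit is not None:
        pre_edit(rw)
    return tag_monomer(rw, site1, site2, head_label=1)


def _assemble_vinyl(assignment, comp_idx, mol,
                    profile_getter) -> AssemblyResult:
    head = _lazy_head(assignment, mol, comp_idx, profile_getter)
    tail = select_tail_atom(assignment, [], head)
    if tail is None:
        return AssemblyResult("tail-unassigned",
                              "no partner atom on the multiple bond")
    rw = RWMol(mol)
    bond = rw.GetBondBetweenAtoms(head, tail)
    if bond.GetBondType() == Chem.BondType.TRIPLE:
        bond.SetBondType(Chem.BondType.DOUBLE)
    elif bond.GetBondType() == Chem.BondType.DOUBLE:
        bond.SetBondType(Chem.BondType.SINGLE)
    else:
        return AssemblyResult("edit-failed",
                              f"matched bond {head}-{tail} is not a multiple bond")
    tm = tag_monomer(rw, head, tail, head_label=1)
    status = "ok" if tm.is_valid else "edit-failed"
    return AssemblyResult(status, tm.message, [tm],
                          [HeadTailAssignment(comp_idx, head, tail)])


def _assemble_ring(assignment, comp_idx, mol,
                   profile_getter) -> AssemblyResult:
    head = _lazy_head(assignment, mol, comp_idx, profile_getter)
    rw, tail, msg = open_ring(mol, head, assignment.polymer_class)
    if msg == "unsupported-topology":
        return AssemblyResult("unsupported-topology",
                              f"head atom {head} is in a fused/bridged ring")
    if tail is None:
        return AssemblyResult("edit-failed", f"ring opening: {msg}")
    # heteroatom end carries [*:2]; the freed carbon end carries [*:1]
    tm = tag_monomer(rw, head, tail, head_label=2)
    status = "ok" if tm.is_valid else "edit-failed"
    return AssemblyResult(status, tm.message, [tm],
                          [HeadTailAssignment(comp_idx, head, tail)])


def _assemble_condensation(assignment, comp_idx, mol, profile_getter,
                           matches) -> AssemblyResult:
    head = _lazy_head(assignment, mol, comp_idx, profile_getter)
    tail = select_tail_atom(assignment, matches, head)
    if tail is None:
        return AssemblyResult("tail-unassigned",
                              "no carboxylic acid / acyl halide for the tail")
    rw, msg = apply_condensation_edits(mol, head, tail, matches)
    if rw is None:
        return AssemblyResult("edit-failed", msg)
    marked = _find_marked(rw)
    tm = tag_monomer(rw, marked[1], marked[2], head_label=1)
    status = "ok" if tm.is_valid else "edit-failed"
    return AssemblyResult(status, tm.message, [tm],
                          [HeadTailAssignment(comp_idx, head, tail)])


def _nucleophile_site(match: FunctionalGroupMatch) -> int:
    # heteroatom position within each nucleophilic SMARTS
    if match.pattern_name in ("primary_amine", "hydroxyl", "secondary_amide",
                              "heterocycle", "ether"):
        return match.atom_indices[0]
    if match.pattern_name == "aliphatic_alcohol":
        return match.atom_indices[1]
    return match.atom_indices[0]


def _assemble_two_component(assignment, mols, matches_per_component,
                            profile_getter) -> AssemblyResult:
    """Copolymer pair: one [*:1] and one [*:2] per polymerizing component.

    The nucleophilic component is tagged on its two most nucleophilic
    sites; the electrophilic component on its two reactive carbons
    (isocyanate carbons gain an N-H on urethane-forming addition, acid
    carbons lose the leaving hydroxyl).
    """
    support = assignment.candidate.supporting_matches
    nuc_names = ("hydroxyl", "primary_amine", "aliphatic_alcohol")
    elec_names = ("isocyanate", "carboxylic_acid", "acyl_halide")
    nuc = [m for m in support if m.pattern_name in nuc_names]
    elec = [m for m in support if m.pattern_name in elec_names]
    nuc_comps = {m.component_index for m in nuc}
    elec_comps = {m.component_index for m in elec} - nuc_comps
    if not nuc_comps or not elec_comps:
        return AssemblyResult("edit-failed",
                              "copolymer route needs separate nucleophilic "
                              "and electrophilic components")
    nc = min(nuc_comps)
    ec = min(elec_comps)

    # --- nucleophilic component: two heteroatom sites, head by R_X ---
    sites = sorted({_nucleophile_site(m) for m in nuc if m.component_index == nc})
    if len(sites) < 2:
        return AssemblyResult("edit-failed",
                              f"component {nc} has {len(sites)} nucleophilic "
                              "site(s); two are needed to chain-extend")
    if len(sites) == 2 and sites[0] == sites[1]:
        head, second = sites[0], sites[1]
    else:
        ranked = _profile_rank(profile_getter(nc), sites)
        head, second = ranked[0], ranked[1]
    tm_nuc = _tag_sites(mols[nc], head, second)
    if not tm_nuc.is_valid:
        return AssemblyResult("edit-failed", tm_nuc.message)

    # --- electrophilic component: two reactive carbons ---
    emol = mols[ec]
    ematches = sorted((m for m in elec if m.component_index == ec),
                      key=lambda m: min(m.atom_indices))
    if len(ematches) < 2:
        return AssemblyResult("edit-failed",
                              f"component {ec} has {len(ematches)} electrophilic "
                              "group(s); two are needed to chain-extend")
    rw = RWMol(emol)
    carbons = []
    removals = []
    for m in ematches[:2]:
        if m.pattern_name == "isocyanate":
            n_idx, c_idx = m.atom_indices[0], m.atom_indices[1]
            rw.GetBondBetweenAtoms(n_idx, c_idx).SetBondType(Chem.BondType.SINGLE)
            carbons.append(c_idx)
        else:
            carbons.append(m.atom_indices[0])
            removals.append(m.atom_indices[2])
    for k, c_idx in enumerate(carbons):
        rw.GetAtomWithIdx(c_idx).SetIntProp(_HEAD_PROP, k + 1)
    for r in sorted(removals, reverse=True):
        rw.RemoveAtom(r)
    marked = _find_marked(rw)
    tm_elec = tag_monomer(rw, marked[1], marked[2], head_label=1)
    if not tm_elec.is_valid:
        return AssemblyResult("edit-failed", tm_elec.message)

    ordered = sorted([(nc, tm_nuc, HeadTailAssignment(nc, head, second)),
                      (ec, tm_elec, HeadTailAssignment(ec, carbons[0], carbons[1]))])
    return AssemblyResult("ok", "",
                          [t[1] for t in ordered], [t[2] for t in ordered])


def assemble_repeat_unit(assignment: ClassAssignment,
                         mols: list[Chem.Mol],
                         matches_per_component: list[list[FunctionalGroupMatch]],
                         profile_getter: ProfileGetter) -> AssemblyResult:
    """Route the classified monomer through the appropriate edit sequence
    and emit tagged repeat-unit SMILES (one [*:1] and one [*:2] per
    polymerizing component)."""
    if assignment.polymer_class == "polyurethane" or (
            assignment.candidate.requires_two_components):
        return _assemble_two_component(assignment, mols,
                                       matches_per_component, profile_getter)

    assignment = _refine_winning_match(assignment, profile_getter)
    comp_idx = assignment.winning_match.component_index
    mol = mols[comp_idx]
    matches = matches_per_component[comp_idx]

    # cross-component condensation (e.g. diamine + diacid)
    if assignment.polymer_class in ("polyamide", "polyester"):
        elec_comps = {m.component_index
                      for comp in matches_per_component for m in comp
                      if m.pattern_name in ("carboxylic_acid", "acyl_halide")}
        if elec_comps and comp_idx not in elec_comps:
            return _assemble_two_component(assignment, mols,
                                           matches_per_component, profile_getter)

    if assignment.polymer_class == "polyvinyl":
        return _assemble_vinyl(assignment, comp_idx, mol, profile_getter)
    if _ring_route(assignment, mol):
        return _assemble_ring(assignment, comp_idx, mol, profile_getter)
    return _assemble_condensation(assignment, comp_idx, mol, profile_getter,
                                  matches)
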