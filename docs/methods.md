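# Methods

## Problem and overall procedure

Polymer-informatics models consume repeat-unit strings (p-SMILES) in
which two atoms per repeat unit are marked as the points of bond
formation during polymerization — the *head* (`[*:1]`) and *tail*
(`[*:2]`).  Most monomer collections lack these marks.  This package
assigns them automatically by combining substructure chemistry with a
one-shot quantum-chemical reactivity calculation:

1. **Monomer identification.**  If the input is a reaction SMILES, each
   reactant is compared with the largest product by Tanimoto similarity
   over RDKit path-based topological fingerprints; the most
   product-like reactant is the monomer.  Multi-component monomer
   records (`A.B`) are treated as copolymer pairs and never merged.
2. **Class candidates.**  Eleven functional-group SMARTS patterns are
   matched on the canonicalized monomer; a rule table licenses up to
   five polymer classes (polyvinyl, polyamide, polyester, polyether,
   polyurethane).
3. **Reactivity ranking.**  When more than one class is licensed — or a
   licensed group contains more than one plausible attachment atom —
   the monomer is embedded in 3D, an RHF/STO-3G wavefunction is
   converged, and every atom X receives the nucleophilicity index

       R_X = p_X / (1 − ε_HOMO)

   where `p_X` is the Mulliken gross population of the HOMO on atom X
   (Σ_X p_X = 1) and `ε_HOMO` is the HOMO energy in hartree.  The class
   whose nucleophilic group hosts the largest R_X wins; the head atom
   is the highest-R_X heavy atom of the winning group.  When only one
   class and one attachment atom are possible, the quantum step is
   skipped entirely.
4. **Mechanism.**  A fixed table: polyvinyl → polyaddition; polyamide
   and polyurethane → polycondensation; polyether → ring opening;
   polyester → polycondensation, or ring opening when the winning group
   sits in a ring.  For polyvinyl *reaction* records the polyaddition
   subcategory (radical / anionic / cationic) is identified by exact
   fingerprint match (similarity = 1.0) of any reactant against a
   configurable initiator table.
5. **Repeat-unit construction.**  All edits are molecular-graph
   operations, never string surgery: double/triple bonds are reduced in
   order (vinyl), one ring bond incident to the head heteroatom is
   deleted (ring opening), leaving hydroxyls/halides are removed as
   atoms (condensation), and the wildcard attachment atoms are added as
   graph nodes.  Every emitted structure must pass full valence
   sanitization; anything that does not is reported as invalid, never
   returned silently.

## Why graph editing

Regex-style SMILES manipulation is known to emit valence-violating
strings for cyclic precursors (pentavalent carbons of the form
`...C(=O)([*:2])O([*:1])`), because a character sequence carries no
connectivity.  Operating on the molecular graph makes ring opening a
single well-defined edge deletion and makes "the emitted SMILES is
valid" a checkable invariant.  This is the main design divergence from
string-based predecessors, and the reason the cyclic fixtures reproduce
their known repeat units exactly.

## The SCF backend

The wavefunction is computed in-process by a compact restricted
Hartree–Fock engine written for this package:

* **Integrals** — McMurchie–Davidson Hermite-Gaussian recursions
  (numba-jitted), Cartesian angular momenta up to *d*, Boys function by
  downward series recursion for T < 35 and erf-based upward recursion
  above, Schwarz screening of two-electron integrals at 1e−12.
* **SCF** — symmetric orthogonalization, core-Hamiltonian guess, DIIS
  (window 8), convergence at |ΔE| < 1e−9 with maximum density change
  < 1e−6; one automatic retry with damping 0.3 plus a 0.3-hartree level
  shift before a convergence error is raised.
* **Basis** — STO-3G for H, C, N, O, F (the published parameters).
  Other elements, bases, and correlated/DFT methods raise informative
  errors rather than guessing; RHF/STO-3G is the level at which the
  ranking protocol is defined and validated, and the R_X *ranking* is
  all the pipeline consumes.
* **Validation** — s-integrals against closed-form Gaussian formulas,
  H₂ at 1.4 bohr against the classic literature energy (−1.1167 Eh,
  reproduced to 7 digits), H₂O dimensions/energy, MO orthonormality
  (max |CᵀSC − I| < 1e−6), Mulliken closure to the electron count, and
  the butadiene terminal-vs-inner HOMO ordering against an independent
  Hückel-chain model.

Geometry: one conformer from seeded distance-geometry embedding
(ETKDGv3, default seed 42) relaxed with UFF capped at 5000 steps.  A
fixed seed makes the whole pipeline deterministic; assignments proved
stable across seeds in practice because rankings, not raw values, drive
every decision.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `seed` | 42 | conformer embedding seed; sole source of randomness |
| `basis` / `method` | STO-3G / RHF | model chemistry (only supported pair) |
| `max_uff_steps` | 5000 | force-field relaxation cap |
| `fix_lactones` | off | adds the lactone `[CX3](=O)[OX2;R]` → polyester rule |
| `patterns_file` | built-in 11 | YAML/JSON SMARTS override |
| `initiators_file` | built-in 8 | YAML/JSON initiator table for vinyl subcategories |

The SMARTS strings themselves are a design choice: the sources describe
the groups pictorially.  The library was chosen so that the documented
classification behavior is reproduced *including its known flaw*: a
cyclic ester carries no free carboxylic-acid proton, so by default a
lactone satisfies only the cyclic-ether rule and is assigned polyether
with a ring-opening mechanism.  `--fix-lactones` opts into the
corrected rule; both behaviors are tested.

## Conventions and tie-breaks

* Atom indices everywhere refer to the canonical SMILES atom order of
  each component (heavy atoms first; hydrogens appended internally).
* Cross-class score ties (the same atom topping two groups) resolve by
  the fixed priority polyvinyl > polyamide > polyester > polyurethane >
  polyether; R_X ties between atoms resolve to the lower index.
* Ring opening: if a ring neighbor of the head heteroatom is an acyl
  carbon (lactone/lactam), the heteroatom–acyl bond is broken;
  otherwise the bond on the less-substituted side (fewer heavy
  neighbors, ties to the lower index) — this is what sends propylene
  oxide's scission away from the methyl-bearing carbon.  Heads in fused
  or bridged rings are refused with an explicit status.
* For ring routes, head eligibility is restricted to the winning
  match's *ring* atoms: a lactam's carbonyl oxygen belongs to the amide
  SMARTS match but cannot be the polymerization point of the ring.
* Tag placement: `[*:1]` on the head for addition/condensation routes;
  for ring-opened units the heteroatom end carries `[*:2]` and the
  carbon end `[*:1]`, matching the published ground-truth strings.
  Validation collapses both tokens to `*`, so this is cosmetic.
* Polyurethane pairs: the diol is tagged on its two hydroxyl oxygens
  (head = higher R_X); each isocyanate N=C is reduced to a single bond
  (the nitrogen regaining a hydrogen) and the carbons are tagged —
  urethane-forming addition, one `[*:1]`/`[*:2]` pair per component.
* Monomer-selection ties keep the first-listed reactant; multi-product
  reactions compare against the largest product by heavy-atom count;
  the Tanimoto of two empty fingerprints is defined as 0.0.

## What the built-in fixtures do and do not show

The twelve worked examples (`headtail.harness.builtin_fixtures`) span
all five classes: two vinyls, a linear and a cyclic amide, four cyclic
ethers/esters with published repeat units, a linear polyester, the two
documented lactone misclassification cases, and a diol/diisocyanate
pair.  They are real monomers with hand-verified expected outputs, kept
small (≤ 13 heavy atoms, ≤ 86 basis functions) so the whole suite runs
in minutes on one CPU — a deliberate problem-size choice.  They do not
exercise: elements beyond H/C/N/O/F, sterically congested vinyls (where
the most nucleophilic site can be blocked — no steric descriptor is
implemented), charged or open-shell species (refused by design), or the
breadth of a curated multi-hundred-monomer collection.  Passing them
demonstrates the machinery and the documented behaviors, not field
accuracy; the full published validation set can be scored with
`scripts/replicate_full_dataset.py` after a separate download.

## Known limitations

* Nucleophilicity only: no LUMO/electrophilicity counterpart, no steric
  (percent-buried-volume) screening, so bulky substituents adjacent to
  the most nucleophilic site can mislead the head choice.
* One observation worth recording: for acrylamide this backend puts the
  largest HOMO population on the amide oxygen, not the vinyl carbons.
  The assignment is unaffected — a lone primary amide licenses no
  class, so polyvinyl is the only candidate and head/tail stay on the
  double bond — but a global "most nucleophilic atom" readout should
  not be over-interpreted; only within-group comparisons drive the
  pipeline.
* Basis library limited to H, C, N, O, F; halogenated monomers beyond
  fluorine classify fine but cannot be quantum-ranked.
* Single conformer; conformer-dependent rankings are possible in
  principle for floppy molecules, though none was observed across
  seeds in the shipped examples.
* Stereochemistry is not guaranteed to survive ring opening.
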