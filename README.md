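# headtail

Automated head/tail atom assignment for polymer repeat-unit SMILES.

Machine-learning models of polymer properties consume repeat-unit
strings (p-SMILES) in which the two atoms that form bonds during
polymerization are tagged — the head `[*:1]` and the tail `[*:2]`.
Monomer collections rarely carry these tags.  Given monomer SMILES (or
full reaction SMILES), this package identifies the monomer, assigns a
polymer class and polymerization mechanism from functional-group SMARTS
rules, ranks candidate reactive sites with a quantum-chemical
nucleophilicity index, performs graph-based ring-opening or
condensation edits, and emits valid tagged repeat-unit SMILES.

The per-atom reactivity score is the atomic nucleophilicity index

$$R_X = \frac{\sum_{\alpha}^{X} |C_{\alpha n}|^2}{1 - \varepsilon_n}
      = \frac{p_X}{1 - \varepsilon_{\mathrm{HOMO}}}$$

where `p_X` is the Mulliken population of the HOMO on atom X and
`ε_HOMO` its energy in hartree, from an RHF/STO-3G calculation on a
seeded, UFF-relaxed conformer.  The SCF (McMurchie–Davidson integrals,
DIIS) runs in-process; no external quantum-chemistry program is needed.
Classes covered: polyvinyl, polyamide, polyester, polyether,
polyurethane — including copolymer pairs such as diol + diisocyanate.

## Worked example

```bash
$ hta fixtures --emit fx          # write the built-in worked examples
12 fixtures -> fx/input.csv, fx/truth.csv
$ hta run --input fx/input.csv --output out.csv --seed 42
12 records processed, 12 ok -> out.csv
$ hta validate --pred out.csv --truth fx/truth.csv --report report.csv
12 entries compared
class accuracy:     1.000
head/tail accuracy: 1.000
  polyamide      2/2
  polyester      1/1
  polyether      6/6
  polyurethane   1/1
  polyvinyl      2/2
```

`out.csv` holds one row per monomer with the class, mechanism, tagged
SMILES and the head/tail atom indices (canonical atom order).  Three
representative rows:

| polymer_name | class | mechanism | tagged_smiles |
|---|---|---|---|
| polyacrylamide | polyvinyl | polyaddition | `NC(=O)C(C[*:1])[*:2]` |
| nylon-10 | polyamide | polycondensation | `O=C(CCCCCCCCCN[*:1])[*:2]` |
| poly(propylene glycol) | polyether | ring_opening | `CC(C[*:1])O[*:2]` |

For acrylamide the tags sit on the two carbons of the former double
bond (chain growth across the vinyl); for the amino-acid nylon
precursor the head is the amine nitrogen and the tail the acyl carbon
with the condensation water already removed; for propylene oxide the
ring is opened on the unsubstituted side, exactly the published repeat
unit.  Validation treats `[*:1]`/`[*:2]` as interchangeable tokens
(both collapse to `*` before canonical comparison), so a head/tail swap
is never an error while any structural difference is.

By default a lactone such as ε-caprolactone is assigned **polyether**
(a cyclic ester carries no free carboxylic acid, so only the
cyclic-ether rule fires) — faithfully reproducing the documented
behavior of the original protocol.  `hta run --fix-lactones` opts into
a corrected lactone → polyester rule; both modes are tested.

The same functionality is available as a library:

```python
from headtail import run_pipeline, PipelineConfig
from headtail.chemio import InputRecord

rows = run_pipeline([InputRecord("PEG", "C1CO1", "monomer")],
                    PipelineConfig(seed=42))
print(rows[0].polymer_class, rows[0].mechanism, rows[0].tagged_smiles)
# polyether ring_opening C(C[*:1])O[*:2]
```

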