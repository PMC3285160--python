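# coatmap

Protein–protein interface detection in low-resolution multi-chain
assemblies, and evolutionary analysis of the detected interfaces.

Large vesicular assemblies such as clathrin coats are often resolved only
at the level of C-alpha coordinates, yet the questions that matter —
*which residues hold the assembly together, and how conserved are they
across species?* — are residue-level questions. `coatmap` implements the
full analysis chain for structural bioinformaticians working on such
systems:

1. **Interface detection from solvent accessibility.** In an all-atom
   complex, residue *i* of chain *c* is an interface residue when

   `rel_acc(i | complex) < 7%  AND  rel_acc(i | chain c alone) > 10%`

   where relative accessibility is Shrake–Rupley ASA (probe 1.4 Å) over a
   per-residue-type reference maximum. For C-alpha-only models the same
   dual criterion is expressed as residue-type-dependent *absolute*
   cutoffs on C-alpha ASA under a coarse 3.5 Å probe, calibrated from
   all-atom structures by isotonic regression of C-alpha ASA on relative
   accessibility, evaluated at 7% and 10%.
2. **Subcomplex decomposition.** Chains are *near neighbors* when any
   inter-chain C-alpha pair is ≤ 5 Å apart; each chain plus its neighbors
   forms a subcomplex analyzed as an independent structure, which makes
   accessibility analysis of 18-chain coats tractable.
3. **Conservation of interfaces.** Orthologue sets filtered at > 30%
   identity and > 70% coverage are scored per column by sequence-weighted
   Shannon entropy (z-normalized; lowest score = most conserved), and the
   mean score of interface residues is compared with non-interface
   surface-exposed residues (bootstrap CI).
4. **Mirror-tree correlated evolution.** Genetic distance matrices
   (Poisson or Gamma ML corrections of the observed difference fraction,
   *d* = −ln(1−p) or *d* = α((1−p)^(−1/α) − 1)) are compared between
   families by Pearson correlation of their upper triangles over common
   species, with a label-permutation significance test and support for
   unrelated-pair baselines; neighbor-joining trees are built from the
   same matrices.

A first-class synthetic-data module generates the study systems these
methods assume: packed-helix complexes with known buried interfaces in
all-atom and C-alpha renditions, and orthologue families evolved along
species trees with slow interface sites and layer-dependent family rates.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```
$ python examples/detect_interface.py
chain  res    type  rel_complex%  rel_isolated%  in_contact_truth
    A  L9     LEU          4.4          50.6  True
    A  D16    ASP          4.9          49.9  True
    A  P20    PRO          2.3          52.1  True
    B  M6     MET          3.3          49.1  True
    ...
```

Each listed residue is buried in the complex (left column, < 7%) but
exposed once its chain is isolated (> 10%), and each lies inside the
independent 5 Å heavy-atom contact ground truth of the generator. And:

```
$ python examples/mirror_trees.py
shared species tree : r = +0.976   permutation p = 0.0010
independent trees  : r = +0.020   permutation p = 0.4320
```

Families evolved on one shared species tree leave strongly correlated
distance matrices; unrelated families do not — the signal used to rank
how strongly each assembly component co-evolves with the clathrin heavy
chain.

The other scripts cover C-alpha-regime detection with calibrated cutoffs
(`calpha_interface.py`), subcomplex decomposition
(`subcomplex_decomposition.py`), and the interface-vs-surface
conservation comparison (`conservation_comparison.py`).

A full pipeline run from one YAML config (structures → interfaces →
conservation → mirror correlations → `report.json`):

```
coatmap run --config examples/run_synthetic.yaml
```

The `coatmap` CLI also exposes the individual stages (`neighbors`,
`sasa`, `interface`, `calibrate`, `conserve`, `mirror`, `simulate`).

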