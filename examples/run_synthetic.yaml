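# Bundled synthetic end-to-end configuration.
#
# Generates a two-chain helix complex, detects its interface in the
# all-atom regime, scores conservation of a simulated orthologue family
# mapped onto chain A, and correlates genetic distance matrices of three
# simulated families (one related pair plus one unrelated baseline pair).
out_dir: scratch/run_synthetic
seed: 123
structures:
  - name: toy_complex
    scenario: {seed: 11}
families:
  - name: clathrin_like
    scenario: {n_taxa: 12, n_sites: 200, seed: 21,
               site_classes: [[interface, 0.3, 0.3], [other, 1.0, 0.7]]}
    structure: toy_complex
    chain: A
  - name: beta_like
    scenario: {n_taxa: 12, n_sites: 200, seed: 21, family_scale: 1.2}
  - name: mu_like
    scenario: {n_taxa: 12, n_sites: 200, seed: 23, family_scale: 2.0}
mirror_pairs:
  - [clathrin_like, beta_like]
baseline_pairs:
  - [clathrin_like, mu_like]
n_permutations: 199
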