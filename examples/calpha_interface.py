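"""Interface detection from C-alpha-only coordinates (cryo-EM regime).

Low-resolution coat structures provide only C-alpha positions, so the
accessibility criterion is re-expressed as residue-type-dependent
absolute cutoffs on C-alpha ASA under a coarse 3.5 A probe. The cutoffs
are calibrated from a corpus of all-atom complexes, then applied to a
held-out complex rendered C-alpha-only; the all-atom detection of the
same complex serves as the reference.
"""

from coatmap.interface import (
    calibrate_calpha_cutoffs,
    detect_interface_allatom,
    detect_interface_calpha,
)
from coatmap.sasa import compute_sasa, isolated_chain_sasa
from coatmap.synthetic import ComplexScenario, generate_complex

training = [generate_complex(ComplexScenario(seed=1000 + k))[0] for k in range(15)]
cutoffs = calibrate_calpha_cutoffs(training, min_train=50)
print("calibrated cutoff sample (A^2 of C-alpha ASA at probe 3.5 A):")
print(cutoffs.to_frame().head(5).to_string(index=False))

allatom, calpha, _ = generate_complex(ComplexScenario(seed=2011))

aa_complex = compute_sasa(allatom, 1.4)
aa_iso = {c.chain_id: isolated_chain_sasa(allatom, c.chain_id, 1.4)
          for c in allatom.chains}
reference = detect_interface_allatom(aa_complex, aa_iso)

ca_complex = compute_sasa(calpha, 3.5)
ca_iso = {c.chain_id: isolated_chain_sasa(calpha, c.chain_id, 3.5)
          for c in calpha.chains}
predicted = detect_interface_calpha(ca_complex, ca_iso, cutoffs)

for cid in allatom.chain_ids:
    ref, pred = reference.chain(cid), predicted.chain(cid)
    tp = len(ref & pred)
    f1 = 2 * tp / (len(ref) + len(pred)) if (ref or pred) else 1.0
    print(f"chain {cid}: all-atom {sorted(r[0] for r in ref)} "
          f"calpha {sorted(r[0] for r in pred)}  F1 = {f1:.2f}")

# The coarse regime recovers most of the all-atom interface from
# C-alpha coordinates alone; per-chain F1 around 0.6-1.0 is typical.
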