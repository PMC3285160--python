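"""Compare conservation of interface vs non-interface surface residues.

An orthologue family is simulated along a species tree with interface
sites evolving at one fifth the rate of the rest, mapped onto chain A of
a generated complex. Conservation scores use the convention that the
lowest score marks the most conserved position, so a negative
interface-minus-surface difference means the interface is the more
conserved class.
"""

from coatmap.conservation import (
    classify_surface,
    compare_interface_conservation,
    conservation_scores,
)
from coatmap.interface import detect_interface_allatom
from coatmap.sasa import compute_sasa, isolated_chain_sasa
from coatmap.synthetic import ComplexScenario, EvolutionScenario, generate_complex, simulate_family

allatom, _, _ = generate_complex(ComplexScenario(seed=11))
complex_profile = compute_sasa(allatom, 1.4)
isolated = {c.chain_id: isolated_chain_sasa(allatom, c.chain_id, 1.4)
            for c in allatom.chains}
interfaces = detect_interface_allatom(complex_profile, isolated)

chain = allatom.chain("A")
# evolve the family so the detected interface positions are the slow sites
iface = interfaces.chain("A")
per_site = [("interface", 0.2) if res.res_id in iface else ("other", 1.0)
            for res in chain.residues]
family = simulate_family(EvolutionScenario(
    n_taxa=16, n_sites=len(chain.residues),
    site_rates_per_site=per_site, seed=5,
))
profile = conservation_scores(family.msa)

partition = classify_surface(isolated["A"], interfaces, "A")
positions = {res.res_id: i + 1 for i, res in enumerate(chain.residues)}
result = compare_interface_conservation(profile, partition, positions, seed=0)

print(f"interface residues:      n={result.n_interface:<3} "
      f"mean score {result.mean_interface:+.3f}")
print(f"surface (non-interface): n={result.n_surface:<3} "
      f"mean score {result.mean_surface:+.3f}")
print(f"difference (interface - surface): {result.difference:+.3f} "
      f"[95% CI {result.ci_low:+.3f}, {result.ci_high:+.3f}]")

# The difference and its bootstrap CI quantify how much better conserved
# the detected interface is than the rest of the chain's surface.
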