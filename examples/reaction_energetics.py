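"""Free-energy bookkeeping for an ylide α-elimination from an external QC table.

The table below is a SYNTHETIC stand-in with made-up energies illustrating the
mechanics: whether an ylide's decomposition into a free carbene plus a sulfide
by-product is endergonic (ΔG > 0, carbene pathway disfavored) is read directly
off externally computed Gibbs energies.  Swap in your own quantum-chemistry
results via spirospace.thermo.parse_energy_table.
"""

from spirospace.thermo import ThermoSpecies, reaction_free_energy

ylide = ThermoSpecies("ylide", -1000.1000, method="m06-2x", basis="def2-svp", solvent="thf")
carbene = ThermoSpecies("carbene", -700.0500, method="m06-2x", basis="def2-svp", solvent="thf")
sulfide = ThermoSpecies("sulfide", -300.0300, method="m06-2x", basis="def2-svp", solvent="thf")

rxn = reaction_free_energy(reactants=[ylide], products=[carbene, sulfide])
print("ylide  ->  carbene + sulfide")
print(f"dG = {rxn.delta_g_kcal:+.1f} kcal/mol "
      f"({'endergonic: alpha-elimination disfavored' if rxn.delta_g_kcal > 0 else 'exergonic'})")
print()
print("Positive dG means the free-carbene route is thermodynamically uphill, the")
print("computational argument for a nucleophilic (carbenoid) mechanism instead.")
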