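"""Mutation-effect scoring: Delta log P = log P_mut - log P_wt.

The score compares the model's probability for the mutant amino acid against
the wild type at one site; positive values mean the mutant fits the
neighborhood better.  A self-mutation scores exactly zero, and swapping the
wild-type and mutant roles negates the score.
"""

from holoprot import (BasisSpec, CGNetwork, MutationSpec, NetworkConfig,
                      build_chain, network_energy, score_mutation)

basis = BasisSpec(l_max=3, n_max=5)
cfg = NetworkConfig(n_layers=1, mode="simply", hidden_channels=5, l_max=2,
                    head_widths=(16,), seed=2)
model = CGNetwork(cfg, basis, ("carbon", "nitrogen", "oxygen"))

chain = build_chain("AAAVLAAKA", phi=-57.0, psi=-47.0)
print(f"chain: {''.join(chain.residue_label(i) for i in range(chain.n_residues))}"
      f"  (ideal helix)")
print(f"network energy E (sum of wild-type pseudoenergies): "
      f"{network_energy(model, chain):+.3f}")

for mut in ("V", "A", "L", "K"):
    s = score_mutation(model, chain, None, MutationSpec("A", 4, "V", mut))
    note = "  <- self-mutation: exactly zero" if mut == "V" else ""
    print(f"V4{mut}: Delta log P = {s.delta_log_p:+.4f} ({s.mode}){note}")

# antisymmetry: the same site seen from the other allele
swapped = build_chain("AAAALAAKA", phi=-57.0, psi=-47.0)
rev = score_mutation(model, swapped, None, MutationSpec("A", 4, "A", "V"))
print(f"A4V on the swapped chain: {rev.delta_log_p:+.4f} "
      f"(negates V4A above: the score is antisymmetric)")
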