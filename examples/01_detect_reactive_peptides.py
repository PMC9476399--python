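"""Detect antibody-reactive peptides in one serum sample.

Builds a small synthetic plate with known spiked-in enrichments, runs
the Bayesian spike-and-slab model for a single serum column against the
beads-only background, and prints the top-ranked peptides.
"""

import numpy as np

import phipbayes as pb

prior = pb.generate_beads_prior(400, seed=1)
design = pb.SampleDesign(n_beads=6, n_serum=1, n_null=0, n_replicate_pairs=0)
plate, truth = pb.simulate_dataset(prior, design=design, seed=2)

config = pb.BeerConfig(n_iter=3000, n_burn=800, seed=3)
summary = pb.run_beer(plate, "serum_1", config=config)

calls = pb.call_enriched(summary, cutoff=0.5)
z = truth.Z_true["serum_1"]
print(f"attenuation c_hat = {summary.c_hat:.3f} "
      f"(true {truth.c_true['serum_1']:.3f})")
print(f"called {int(calls.sum())} peptides enriched; "
      f"{int((calls & z).sum())} of the {int(z.sum())} spikes recovered, "
      f"{int((calls & ~z).sum())} false positives")
print(f"{int(summary.table['excluded'].sum())} super-enriched peptides "
      "were pre-filtered (reported with posterior probability 1)\n")

top = summary.table.sort_values("post_prob", ascending=False).head(8)
top = top.assign(true_phi=truth.phi_true.loc[top.index, "serum_1"])
print("top peptides (post_prob = probability of antibody reactivity,")
print("phi_hat = posterior fold change vs. beads background):")
print(top.round(3).to_string())
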