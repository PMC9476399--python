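"""Simulate a full PhIP-Seq plate and inspect its structure.

The default design mirrors a simulation-study plate: 8 beads-only
columns and 12 serum columns, of which one is a beads-only sample run
as serum (a built-in null) and two are technical replicates sharing the
same enrichment parameters.
"""

import numpy as np

import phipbayes as pb

prior = pb.generate_beads_prior(1000, seed=7)
mu = prior.mu0
print("background composition (proportions sum to 1):")
print(f"  1st/50th/99th percentile of mu_0: "
      f"{np.quantile(mu, 0.01):.2e} / {np.median(mu):.2e} / "
      f"{np.quantile(mu, 0.99):.2e}")
binom = mu * (1 - mu) / 1e6
print(f"  peptides overdispersed vs binomial at 1e6 reads: "
      f"{(prior.sigma2_0 > binom).mean():.1%}\n")

plate, truth = pb.simulate_dataset(prior, seed=8)
print(f"plate: {plate.counts.shape[0]} peptides x "
      f"{plate.counts.shape[1]} samples "
      f"({len(plate.beads_ids)} beads-only, {len(plate.serum_ids)} serum)")
print(f"library sizes: {plate.library_sizes.min():,} - "
      f"{plate.library_sizes.max():,} reads")

enriched = truth.Z_true.sum()
null_cols = list(enriched.index[enriched == 0])
print(f"null column (beads run as serum): {null_cols}")
print(f"spiked peptides per serum column: "
      f"{sorted(set(enriched[enriched > 0]))} (10 per fold-change bin)")
print(f"serum attenuation constants c: "
      f"{truth.c_true[truth.c_true < 1].round(3).to_dict()}")
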