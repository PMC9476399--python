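"""Evaluate both methods with ROC curves and a power regression.

Scores one simulated plate with the Bayesian model and the exact test,
computes the fold-change-bin ROC AUCs, an FDR-matched posterior cutoff,
and the logistic power curve giving the fold change detectable with 50%
probability.
"""

import numpy as np

import phipbayes as pb
from phipbayes.workflows import pooled_bin_scores

prior = pb.generate_beads_prior(600, seed=21)
design = pb.SampleDesign(n_beads=8, n_serum=2, n_null=0, n_replicate_pairs=0)
plate, truth = pb.simulate_dataset(prior, design=design, seed=22)

config = pb.BeerConfig(n_iter=3000, n_burn=800, seed=23)
beer = pb.run_plate(plate, "beer", config=config, seed=23).pivot(
    index="peptide_id", columns="sample_id", values="post_prob"
).reindex(plate.peptide_ids)
nb = 1.0 - pb.run_plate(plate, "nb").pivot(
    index="peptide_id", columns="sample_id", values="p_one"
).reindex(plate.peptide_ids)

print("ROC AUC by true fold-change bin (trapezoid on interpolated curves):")
for lo, hi in [(1, 2), (2, 4), (4, 8), (8, 16)]:
    aucs = {}
    for name, score in [("BEER", beer), ("NB", nb)]:
        s, t = pooled_bin_scores(score, truth, lo, hi)
        roc, _ = pb.roc_pr_curves([s], [t])
        aucs[name] = roc.mean_auc
    print(f"  ({lo:>2},{hi:>2}]: BEER {aucs['BEER']:.3f}   "
          f"NB {aucs['NB']:.3f}")

# FDR-matched posterior cutoff, then power as a function of fold change
s, t = pooled_bin_scores(beer, truth, 1, 32)
cut = pb.fdr_matched_cutoff(s, t, target=0.05)
print(f"\nposterior cutoff for a 5% false-discovery proportion: {cut:.3f}")

col = truth.Z_true.columns[0]
z = truth.Z_true[col].to_numpy()
detected = (beer[col].to_numpy() > cut)[z]
fc = truth.phi_true[col].to_numpy()[z]
_, fc50, separated = pb.power_curve(detected, fc)
note = " (complete separation)" if separated else ""
print(f"fold change detected with 50% probability: {fc50:.2f}{note}")
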