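"""High-level pipelines: one call per analysis the package supports.

These wrap the lower-level modules in the order a user would run them:
estimate the beads-only prior, pre-filter super-enriched peptides, run
the sampler (or the exact-test comparator), and collect tidy per-peptide
results.  The simulation benchmark used to validate discriminatory power
also lives here.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import evaluate as ev
from .model import (
    BeerConfig,
    PosteriorSummary,
    call_enriched,
    prefilter_super_enriched,
    run_mcmc,
)
from .nb import TestResult, nb_test
from .phipdata import PeptideCountMatrix
from .priors import BeadsPrior, estimate_prior
from .simulate import (
    BeadsMeta,
    SampleDesign,
    SimTruth,
    generate_beads_prior,
    simulate_dataset,
)


def run_beer(
    m: PeptideCountMatrix,
    serum: str,
    config: BeerConfig | None = None,
    prior_method: str = "edger",
    prior: BeadsPrior | None = None,
) -> PosteriorSummary:
    """Full Bayesian pipeline for one serum sample.

    Estimates the beads prior (dispersion-derived by default), removes
    super-enriched peptides (initial fold change above the configured
    threshold) from all columns with library sizes recomputed,
    re-estimates the prior on the filtered plate, and runs the Gibbs
    sampler.  Excluded peptides re-enter the summary with posterior
    probability 1 and their initial fold-change estimate.
    """
    config = config or BeerConfig()
    if prior is None:
        prior = estimate_prior(m, prior_method)
    filtered, excluded = prefilter_super_enriched(
        m, prior, serum, config.prefilter_threshold
    )
    if len(excluded):
        prior_f = estimate_prior(filtered, prior_method)
    else:
        prior_f = prior.reindex(filtered.peptide_ids)
    summary = run_mcmc(filtered, prior_f, config, serum, excluded=excluded)
    summary.table = summary.table.reindex(m.peptide_ids)
    return summary


def run_nb(
    m: PeptideCountMatrix, serum: str, alpha: float = 0.05
) -> TestResult:
    """Exact-test comparator pipeline for one serum sample."""
    return nb_test(m, serum, alpha=alpha)


def run_plate(
    m: PeptideCountMatrix,
    method: str = "beer",
    config: BeerConfig | None = None,
    alpha: float = 0.05,
    cutoff: float = 0.5,
    prior_method: str = "edger",
    seed: int = 0,
) -> pd.DataFrame:
    """Analyze every serum column; one tidy row per peptide x sample.

    For the Bayesian method each serum sample gets its own chain with a
    seed derived from ``seed`` and the column position.
    """
    rows = []
    config = config or BeerConfig()
    if method == "beer":
        prior = estimate_prior(m, prior_method)
    else:
        prior = None
    for j, s in enumerate(m.serum_ids):
        if method == "beer":
            cfg = dataclasses.replace(config, seed=(seed + 9973 * j) % 2**31)
            summ = run_beer(
                m, s, config=cfg, prior_method=prior_method, prior=prior
            )
            calls = call_enriched(summ, cutoff)
            df = pd.DataFrame(
                {
                    "peptide_id": summ.table.index,
                    "sample_id": s,
                    "post_prob": summ.table["post_prob"].to_numpy(),
                    "phi_hat": summ.table["phi_hat"].to_numpy(),
                    "excluded": summ.table["excluded"].to_numpy(),
                    "called": calls.to_numpy(),
                }
            )
        elif method == "nb":
            res = run_nb(m, s, alpha=alpha)
            df = res.table.reset_index(names="peptide_id")
            df.insert(1, "sample_id", s)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# simulation benchmark


def pooled_bin_scores(
    score: pd.DataFrame,
    truth: SimTruth,
    lo: float,
    hi: float,
    exclude_null_columns: bool = True,
):
    """Pool scores over serum columns for one fold-change bin.

    Positives are enriched peptides with true fold change in (lo, hi];
    negatives are all non-enriched peptides from the same serum columns.
    Enriched peptides outside the bin are dropped, and beads-run-as-
    serum null columns can be excluded (no enrichment was simulated
    there, so they contribute no positives by construction).
    """
    s_list, t_list = [], []
    for col in score.columns:
        if exclude_null_columns and not truth.Z_true[col].any():
            continue
        z = truth.Z_true[col].to_numpy()
        phi = truth.phi_true[col].to_numpy()
        in_bin = z & (phi > lo) & (phi <= hi)
        keep = in_bin | ~z
        s_list.append(score[col].to_numpy()[keep])
        t_list.append(in_bin[keep])
    return np.concatenate(s_list), np.concatenate(t_list)


def simulation_auc_benchmark(
    seed: int = 1,
    n_datasets: int = 2,
    n_peptides: int = 1000,
    design: SampleDesign | None = None,
    config: BeerConfig | None = None,
    fc_bin: tuple[float, float] = (4.0, 16.0),
) -> dict:
    """ROC AUC of both methods on simulated plates, one fold-change bin.

    Simulates ``n_datasets`` plates from a synthetic beads background
    (default: 8 beads-only + 3 independent serum columns, 50 spiked
    peptides per serum column with 10 per fold-change bin, library sizes
    uniform in [1e6, 2e6]), scores every peptide by posterior
    probability (Bayesian model) and by one minus the one-sided p-value
    (exact test), pools enriched peptides with fold change in ``fc_bin``
    against all non-enriched serum-column peptides, and reports the
    per-dataset trapezoidal ROC AUCs and their means.
    """
    design = design or SampleDesign(
        n_beads=8, n_serum=3, n_null=0, n_replicate_pairs=0
    )
    config = config or BeerConfig()
    beer_scores, beer_truth = [], []
    nb_scores, nb_truth = [], []
    n_scored = 0
    for d in range(n_datasets):
        ds_seed = (seed + 7919 * d) % 2**31
        prior = generate_beads_prior(n_peptides, seed=ds_seed)
        m, truth = simulate_dataset(
            prior, config=config, design=design, seed=ds_seed + 1
        )
        beer_tab = run_plate(
            m, "beer", config=config, seed=ds_seed + 2
        ).pivot(index="peptide_id", columns="sample_id", values="post_prob")
        nb_tab = run_plate(m, "nb").pivot(
            index="peptide_id", columns="sample_id", values="p_one"
        )
        beer_tab = beer_tab.reindex(m.peptide_ids)
        nb_tab = 1.0 - nb_tab.reindex(m.peptide_ids)
        lo, hi = fc_bin
        s, t = pooled_bin_scores(beer_tab, truth, lo, hi)
        beer_scores.append(s)
        beer_truth.append(t)
        s, t = pooled_bin_scores(nb_tab, truth, lo, hi)
        nb_scores.append(s)
        nb_truth.append(t)
        n_scored += t.size
    roc_beer, _ = ev.roc_pr_curves(beer_scores, beer_truth)
    roc_nb, _ = ev.roc_pr_curves(nb_scores, nb_truth)
    return {
        "beer_auc": roc_beer.mean_auc,
        "nb_auc": roc_nb.mean_auc,
        "beer_auc_per_dataset": roc_beer.auc.tolist(),
        "nb_auc_per_dataset": roc_nb.auc.tolist(),
        "n_scored": n_scored,
    }
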