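import numpy as np
import pandas as pd
import pytest

from phipbayes.phipdata import PeptideCountMatrix


@pytest.fixture
def toy_matrix():
    """3 peptides x 4 samples (3 beads + 1 serum) with easy numbers."""
    counts = pd.DataFrame(
        {
            "b1": [100, 850, 50],
            "b2": [200, 700, 100],
            "b3": [300, 550, 150],
            "s1": [500, 400, 100],
        },
        index=["pepA", "pepB", "pepC"],
    )
    roles = pd.Series(
        {"b1": "beads", "b2": "beads", "b3": "beads", "s1": "serum"}
    )
    return PeptideCountMatrix(counts, roles)


def make_plate(rng, n_peptides, beads, serum, mu=None, tau=0.05,
               lib=1_000_000):
    """Overdispersed (gamma-poisson) null plate with known structure."""
    if mu is None:
        mu = rng.lognormal(np.log(lib / n_peptides), 1.0, n_peptides)
    cols = [f"b{j}" for j in range(beads)] + [f"s{j}" for j in range(serum)]
    lam = rng.gamma(1.0 / tau, tau * mu[:, None], (n_peptides, len(cols)))
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=[f"p{i:04d}" for i in range(n_peptides)],
        columns=cols,
    )
    roles = pd.Series(
        ["beads"] * beads + ["serum"] * serum, index=pd.Index(cols)
    )
    return PeptideCountMatrix(counts, roles)


@pytest.fixture(scope="session")
def estimated_plate():
    """Plate simulated from an estimated beads prior, with truth.

    Mirrors the simulation-study procedure: build a synthetic 'real'
    plate, estimate its beads prior through the default empirical-Bayes
    route, then simulate the evaluation plate from those estimates.
    """
    import phipbayes as pb

    raw = pb.generate_beads_prior(600, seed=11)
    stage1 = pb.SampleDesign(
        n_beads=8, n_serum=1, n_null=1, n_replicate_pairs=0
    )
    plate0, _ = pb.simulate_dataset(raw, design=stage1, seed=12)
    est = pb.estimate_prior(plate0, "edger")
    design = pb.SampleDesign(
        n_beads=8, n_serum=2, n_null=0, n_replicate_pairs=0
    )
    m, truth = pb.simulate_dataset(est, design=design, seed=13)
    return m, truth, est


@pytest.fixture(scope="session")
def beer_run(estimated_plate):
    """BEER posterior summaries for both serum columns of the plate."""
    import phipbayes as pb

    m, truth, _ = estimated_plate
    cfg = pb.BeerConfig(n_iter=3000, n_burn=800, seed=5)
    out = {}
    for j, s in enumerate(m.serum_ids):
        import dataclasses

        cfg_j = dataclasses.replace(cfg, seed=5 + j)
        out[s] = pb.run_beer(m, s, config=cfg_j)
    return m, truth, out
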