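"""Synthetic PhIP-Seq plate generator.

Two layers: a beads-background generator that emulates the statistical
structure of real mock IPs — per-peptide background proportions spanning
orders of magnitude (log-normal spread) and between-sample variability
well above binomial at million-read library sizes — and a plate
simulator that spikes known fold-change enrichments into serum columns
under the same beta-binomial generative model the detection method
assumes.

The default plate design is eight beads-only columns and twelve serum
columns: one beads-only sample run as a serum sample (a built-in null),
one technical-replicate pair sharing the same enrichment parameters, and
nine independent serum samples.  Each serum sample has 50 reactive
peptides, ten in each fold-change bin (1,2], (2,4], (4,8], (8,16],
(16,32], with fold changes drawn uniformly within the bin.  Library
sizes are uniform over [1e6, 2e6] reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BeerConfig, _beta_shapes
from .phipdata import PeptideCountMatrix, BEADS, SERUM
from .priors import BeadsPrior, apply_guard, beta_shapes_from_moments

DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (1, 2), (2, 4), (4, 8), (8, 16), (16, 32),
)


@dataclass
class BeadsMeta:
    """Spread parameters of the synthetic beads background.

    ``mu_sigma`` is the log-normal sigma of the raw peptide propensities
    (1.5 gives roughly three orders of magnitude between the 1st and 99th
    percentile of background proportions, as seen on real plates).
    Per-peptide overdispersion (squared coefficient of variation of the
    read-pull probability between mock IPs) is Gamma(``tau_shape``,
    rate ``tau_rate``) — mean 0.1, i.e. a between-sample CV around 30%,
    comparable to biological-replicate variability in count-sequencing
    assays — plus an abundance-linked floor ``tau_floor_reads / mu`` that
    keeps even the rarest peptides overdispersed relative to binomial
    sampling at million-read depth.
    """

    mu_sigma: float = 1.5
    tau_shape: float = 2.0
    tau_rate: float = 20.0
    tau_floor_reads: float = 2e-6

    def __post_init__(self) -> None:
        if self.mu_sigma <= 0 or self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("spread parameters must be positive")


@dataclass
class SampleDesign:
    """Plate layout for :func:`simulate_dataset`."""

    n_beads: int = 8
    n_serum: int = 12
    n_null: int = 1  # beads-only sample run as serum
    n_replicate_pairs: int = 1
    n_enriched_per_bin: int = 10
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS
    library_size_range: tuple[float, float] = (1_000_000, 2_000_000)

    def __post_init__(self) -> None:
        if self.n_null + 2 * self.n_replicate_pairs > self.n_serum:
            raise ValueError("design has more special columns than serum")

    @property
    def n_enriched(self) -> int:
        return self.n_enriched_per_bin * len(self.bins)


@dataclass
class SimTruth:
    """Ground truth for simulated serum columns."""

    Z_true: pd.DataFrame  # peptides x serum samples, bool
    phi_true: pd.DataFrame  # peptides x serum samples, 1 where not enriched
    bins: pd.DataFrame  # columns: sample_id, peptide_id, lo, hi
    c_true: pd.Series  # attenuation per serum sample

    def to_tsv(self, path) -> None:
        long = self.phi_true.stack().rename("phi_true").reset_index()
        long.columns = ["peptide_id", "sample_id", "phi_true"]
        long["Z_true"] = self.Z_true.stack().reset_index(drop=True)
        long.to_csv(path, sep="\t", index=False)


def generate_beads_prior(
    P: int, seed: int, meta: BeadsMeta | None = None
) -> BeadsPrior:
    """Synthetic per-peptide background Beta parameters.

    Mean proportions are normalized log-normal draws (they sum to 1), so
    a plate's background composition is heavy-tailed: a few peptides
    dominate the library while most pull only a handful of reads per
    million.  Variances are ``tau * mu^2`` with the overdispersion law
    described in :class:`BeadsMeta`.
    """
    if P < 2:
        raise ValueError("need at least 2 peptides")
    meta = meta or BeadsMeta()
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=meta.mu_sigma, size=P)
    mu = raw / raw.sum()
    tau = rng.gamma(meta.tau_shape, 1.0 / meta.tau_rate, size=P)
    tau = tau + meta.tau_floor_reads / mu
    sigma2 = tau * mu**2
    if np.any(sigma2 >= mu * (1 - mu)):
        raise ValueError("infeasible spread parameters: variance bound hit")
    a, b = beta_shapes_from_moments(mu, sigma2)
    a, b = apply_guard(a, b)
    ids = [f"pep_{i:05d}" for i in range(P)]
    return BeadsPrior.from_shapes(ids, a, b, "true")


def _draw_counts(rng, mu_mean, sigma2, n_reads):
    """theta ~ Beta(f_a, f_b), Y ~ Binomial(n, theta), clipped feasible."""
    mu_mean = np.clip(mu_mean, 1e-12, 1 - 1e-9)
    bad = sigma2 >= mu_mean * (1 - mu_mean)
    if bad.any():
        import warnings

        warnings.warn(
            f"{int(bad.sum())} peptide(s) hit the Beta variance bound; "
            "their variance was clipped",
            stacklevel=2,
        )
        sigma2 = np.where(bad, 0.99 * mu_mean * (1 - mu_mean), sigma2)
    a, b = _beta_shapes(mu_mean, sigma2)
    theta = rng.beta(a, b)
    return rng.binomial(int(n_reads), theta)


def simulate_dataset(
    prior: BeadsPrior,
    config: BeerConfig | None = None,
    design: SampleDesign | None = None,
    seed: int = 0,
) -> tuple[PeptideCountMatrix, SimTruth]:
    """Simulate one plate under the generative model.

    Beads columns (and the beads-run-as-serum null column) have
    attenuation 1 and no enrichment.  Each remaining serum column draws
    its attenuation from Beta(a_c, b_c), picks ``n_enriched`` peptides
    uniformly, assigns fold changes uniformly within each bin, and then
    draws read-pull probabilities and binomial counts.  Technical
    replicates reuse the same (Z, phi, c) with fresh probability and
    count noise.  Library sizes of the returned matrix are the realized
    column sums.
    """
    config = config or BeerConfig()
    design = design or SampleDesign()
    rng = np.random.default_rng(seed)
    mu0 = prior.mu0
    s20 = prior.sigma2_0
    P = mu0.size
    if design.n_enriched > P:
        raise ValueError("more enriched peptides than peptides")

    beads_ids = [f"beads_{j + 1}" for j in range(design.n_beads)]
    serum_ids = [f"serum_{j + 1}" for j in range(design.n_serum)]
    n_special = design.n_null + 2 * design.n_replicate_pairs

    cols: dict[str, np.ndarray] = {}
    lo_n, hi_n = design.library_size_range
    for s in beads_ids:
        n = int(rng.uniform(lo_n, hi_n))
        cols[s] = _draw_counts(rng, mu0, s20, n)

    Z_true = pd.DataFrame(
        False, index=prior.peptide_ids, columns=serum_ids
    )
    phi_true = pd.DataFrame(
        1.0, index=prior.peptide_ids, columns=serum_ids
    )
    bin_rows = []
    c_true = pd.Series(1.0, index=pd.Index(serum_ids, name="sample_id"))

    def draw_enrichment():
        c = float(rng.beta(config.a_c, config.b_c))
        idx = rng.choice(P, size=design.n_enriched, replace=False)
        phi = np.ones(P)
        z = np.zeros(P, dtype=bool)
        z[idx] = True
        rows = []
        for k, (lo, hi) in enumerate(design.bins):
            sel = idx[
                k * design.n_enriched_per_bin:
                (k + 1) * design.n_enriched_per_bin
            ]
            phi[sel] = rng.uniform(lo, hi, size=sel.size)
            rows.extend((prior.peptide_ids[i], lo, hi) for i in sel)
        return c, z, phi, rows

    # column roles within the serum block
    kinds: list[tuple[str, int]] = []
    for j in range(design.n_null):
        kinds.append(("null", -1))
    for j in range(design.n_replicate_pairs):
        kinds.append(("rep", j))
        kinds.append(("rep", j))
    while len(kinds) < design.n_serum:
        kinds.append(("indep", -1))

    rep_params: dict[int, tuple] = {}
    for s, (kind, ridx) in zip(serum_ids, kinds):
        n = int(rng.uniform(lo_n, hi_n))
        if kind == "null":
            cols[s] = _draw_counts(rng, mu0, s20, n)
            continue
        if kind == "rep":
            if ridx not in rep_params:
                rep_params[ridx] = draw_enrichment()
            c, z, phi, rows = rep_params[ridx]
        else:
            c, z, phi, rows = draw_enrichment()
        c_true[s] = c
        Z_true[s] = z
        phi_true[s] = phi
        bin_rows.extend((s, pid, lo, hi) for pid, lo, hi in rows)
        cols[s] = _draw_counts(rng, c * phi * mu0, s20, n)

    counts = pd.DataFrame(cols, index=prior.peptide_ids)
    roles = pd.Series(
        [BEADS] * design.n_beads + [SERUM] * design.n_serum,
        index=pd.Index(beads_ids + serum_ids),
    )
    m = PeptideCountMatrix(counts, roles)
    truth = SimTruth(
        Z_true=Z_true,
        phi_true=phi_true,
        bins=pd.DataFrame(
            bin_rows, columns=["sample_id", "peptide_id", "lo", "hi"]
        ),
        c_true=c_true,
    )
    return m, truth
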