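"""Beta-binomial spike-and-slab model of peptide antibody enrichment.

For one serum sample with library size :math:`n` the read count of
peptide :math:`i` is modelled hierarchically:

.. math::

    Y_i \\mid \\theta_i &\\sim \\mathrm{Binomial}(n, \\theta_i) \\\\
    \\theta_i &\\sim \\mathrm{Beta}\\bigl(f_a(c\\,\\phi_i\\,\\mu_{i0},
        \\sigma^2_{i0}),\\; f_b(c\\,\\phi_i\\,\\mu_{i0},
        \\sigma^2_{i0})\\bigr) \\\\
    c &\\sim \\mathrm{Beta}(a_c, b_c) \\\\
    \\phi_i \\mid Z_i &\\sim (1 - Z_i)\\cdot 1 + Z_i\\,(\\phi_{\\min}
        + \\Gamma(a_\\phi, b_\\phi)) \\\\
    Z_i \\mid \\pi &\\sim \\mathrm{Bernoulli}(\\pi), \\qquad
    \\pi \\sim \\mathrm{Beta}(a_\\pi, b_\\pi)

where :math:`(\\mu_{i0}, \\sigma^2_{i0})` are the beads-only background
moments, :math:`\\phi_i` the fold change (1 for non-reactive peptides),
:math:`c` the sample-level attenuation constant (reactive peptides
consume reads, depressing everyone else's proportion), and :math:`Z_i`
the enrichment indicator whose posterior mean is the reported
probability of reactivity.

Sampling is Gibbs with a conjugate Beta update for :math:`\\theta`, a
Metropolis-within-Gibbs update of :math:`(Z_i, \\phi_i)` with
:math:`\\theta_i` integrated out through the beta-binomial marginal,
slice sampling for :math:`c`, and a conjugate Beta update for
:math:`\\pi`.  Extremely reactive peptides (initial fold-change estimate
above a threshold, default 15) are removed before sampling — their reads
are dropped from every column and library sizes recomputed — and
reported with posterior probability 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .phipdata import PeptideCountMatrix, BEADS
from .priors import BeadsPrior

_THETA_FLOOR = 1e-12


@dataclass
class BeerConfig:
    """Hyperparameters and chain settings.

    The defaults encode the applied choices: enrichment proportion prior
    Beta(2, 300) (a fraction of a percent of peptides reactive, but
    diffuse), fold-change slab 1 + Gamma(1.25, rate 0.1) (mean 13.5),
    attenuation prior Beta(80, 20) (mean 0.8), minimum enriched fold
    change 1, and a super-enriched pre-filter at initial fold change 15.
    """

    a_pi: float = 2.0
    b_pi: float = 300.0
    a_phi: float = 1.25
    b_phi: float = 0.1
    phi_min: float = 1.0
    a_c: float = 80.0
    b_c: float = 20.0
    prefilter_threshold: float = 15.0
    n_iter: int = 10_000
    n_burn: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a_pi", "b_pi", "a_phi", "b_phi", "a_c", "b_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.phi_min < 1:
            raise ValueError("phi_min must be >= 1")
        if self.prefilter_threshold <= self.phi_min:
            raise ValueError("prefilter_threshold must exceed phi_min")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BeerConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class ChainState:
    """Current values of all sampled quantities for one serum sample."""

    theta: np.ndarray
    Z: np.ndarray  # bool
    phi: np.ndarray
    c: float
    pi: float


@dataclass
class PosteriorSummary:
    """Ergodic means over post-burn-in iterations.

    ``post_prob`` is the posterior mean of the enrichment indicator;
    ``phi_hat`` the posterior mean fold change given enrichment (1 for
    peptides never sampled as enriched); ``excluded`` marks
    super-enriched peptides removed before sampling, which carry
    ``post_prob`` exactly 1 and their initial fold-change estimate.
    """

    table: pd.DataFrame  # post_prob, phi_hat, excluded
    sample_id: str
    c_hat: float
    pi_hat: float
    n_iter: int
    n_burn: int
    seed: int

    @property
    def post_prob(self) -> pd.Series:
        return self.table["post_prob"]

    @property
    def phi_hat(self) -> pd.Series:
        return self.table["phi_hat"]


def call_enriched(s: PosteriorSummary, cutoff: float = 0.5) -> pd.Series:
    """Boolean enrichment calls at a posterior-probability cutoff.

    Pre-filtered super-enriched peptides are always called.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    calls = (s.table["post_prob"] > cutoff) | s.table["excluded"]
    return calls


# ----------------------------------------------------------------------
# initialization and pre-filter


def _init_quantities(m: PeptideCountMatrix, prior: BeadsPrior, serum: str):
    prior = prior.reindex(m.peptide_ids)
    Y = m.counts[serum].to_numpy(dtype=float)
    n = float(m.library_sizes[serum])
    mu0 = prior.mu0
    expected = n * mu0
    # counts are integers; the tiny slack absorbs float round-off in 2*n*mu0
    Z = (Y >= 2.0 * expected - 1e-6) & (Y > 0)
    denom = np.sum((1 - Z) * expected**2)
    if denom > 0:
        c = float(np.sum((1 - Z) * Y * expected) / denom)
    else:
        c = 1.0
    c_raw = c
    c = min(max(c, 1e-4), 1.0 - 1e-4)
    phi = np.ones_like(Y)
    phi[Z] = Y[Z] / (n * c * mu0[Z])
    return Y, n, prior, Z, c, c_raw, phi


def initialize_chain(
    m: PeptideCountMatrix,
    prior: BeadsPrior,
    serum: str,
    offset: float = 1e-4,
) -> ChainState:
    """Starting values from plug-in maximum likelihood estimates.

    ``theta`` starts at the observed proportions; ``Z`` at the indicator
    of the observed count being at least twice the expected beads-only
    count; ``c`` at the through-origin regression slope of observed on
    expected counts over non-enriched peptides; ``phi`` at 1 for
    non-enriched peptides and the attenuation-corrected count ratio
    otherwise; ``pi`` at the fraction of enriched starts.  Since ``c``
    and ``pi`` live on the open unit interval, small offsets move
    boundary values (``c = 1``, ``pi = 0``) inside.
    """
    if serum in m.sample_ids and m.roles.loc[serum] == BEADS:
        warnings.warn(
            f"{serum!r} is a beads-only sample; analyzing it as serum "
            "(round-robin mode)",
            stacklevel=2,
        )
    Y, n, prior, Z, c, c_raw, phi = _init_quantities(m, prior, serum)
    if c_raw >= 1.0:
        c = 1.0 - offset
    pi = float(Z.mean())
    if pi == 0.0:
        pi = 1.0 / m.n_peptides
    pi = min(pi, 1.0 - 1.0 / m.n_peptides)
    theta = np.clip(Y / n if n > 0 else prior.mu0,
                    _THETA_FLOOR, 1 - _THETA_FLOOR)
    return ChainState(theta=theta, Z=Z.copy(), phi=phi, c=c, pi=pi)


def prefilter_super_enriched(
    m: PeptideCountMatrix,
    prior: BeadsPrior,
    serum: str,
    threshold: float = 15.0,
):
    """Remove clearly enriched peptides before starting the chain.

    Peptides whose initial fold-change estimate exceeds ``threshold`` are
    dropped from *every* column (their reads would distort the
    attenuation constant and slow mixing), and library sizes are
    recomputed.  Returns the filtered matrix and a Series of initial
    fold-change estimates for the excluded peptides, which downstream
    reporting re-inserts with posterior probability 1.
    """
    _, _, _, _, _, _, phi = _init_quantities(m, prior, serum)
    mask = phi > threshold
    excluded = pd.Series(
        phi[mask], index=m.peptide_ids[mask], name="phi_init"
    )
    if not mask.any():
        return m, excluded
    return m.drop_peptides(list(excluded.index)), excluded


# ----------------------------------------------------------------------
# sampler internals


def _beta_shapes(mean: np.ndarray, sigma2: np.ndarray):
    """Vectorized f_a/f_b with non-positive shapes marking infeasibility."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = mean**2 * (1 - mean) / sigma2 - mean
        b = a * (1 / mean - 1)
    return a, b


class _Sampler:
    """Vectorized Gibbs sampler for a single serum sample."""

    def __init__(self, Y, n, mu0, sigma2_0, config: BeerConfig, rng):
        self.Y = np.asarray(Y, float)
        self.n = float(n)
        self.mu0 = np.asarray(mu0, float)
        self.s20 = np.asarray(sigma2_0, float)
        self.cfg = config
        self.rng = rng
        self.P = self.Y.size

    # marginal log-likelihood of Y with theta integrated out
    def log_marginal(self, phi: np.ndarray, c: float) -> np.ndarray:
        mean = c * phi * self.mu0
        a, b = _beta_shapes(mean, self.s20)
        ok = (mean > 0) & (mean < 1) & (a > 0) & (b > 0)
        out = np.full(self.P, -np.inf)
        if ok.any():
            ao, bo = a[ok], b[ok]
            yo = self.Y[ok]
            out[ok] = special.betaln(ao + yo, bo + self.n - yo) - \
                special.betaln(ao, bo)
        return out

    def log_theta_prior(self, theta, phi, c) -> np.ndarray:
        mean = c * phi * self.mu0
        a, b = _beta_shapes(mean, self.s20)
        ok = (mean > 0) & (mean < 1) & (a > 0) & (b > 0)
        out = np.full(self.P, -np.inf)
        if ok.any():
            ao, bo = a[ok], b[ok]
            t = theta[ok]
            out[ok] = (
                (ao - 1) * np.log(t)
                + (bo - 1) * np.log1p(-t)
                - special.betaln(ao, bo)
            )
        return out

    def draw_slab(self, size: int) -> np.ndarray:
        g = self.rng.gamma(self.cfg.a_phi, 1.0 / self.cfg.b_phi, size=size)
        return self.cfg.phi_min + g

    def log_slab_pdf(self, phi: np.ndarray) -> np.ndarray:
        x = phi - self.cfg.phi_min
        a, rate = self.cfg.a_phi, self.cfg.b_phi
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                x > 0,
                a * np.log(rate) + (a - 1) * np.log(x) - rate * x
                - special.gammaln(a),
                -np.inf,
            )

    # ------------------------------------------------------------------
    def update_z_phi(self, state: ChainState, lm_cur: np.ndarray):
        """Joint flip of (Z, phi) with theta collapsed, then two
        within-slab refreshes (independence and multiplicative random
        walk) for currently enriched peptides."""
        cfg, rng = self.cfg, self.rng
        Z, phi, c, pi = state.Z, state.phi, state.c, state.pi
        logit_pi = np.log(pi) - np.log1p(-pi)

        lm_one = self.log_marginal(np.ones(self.P), c)
        phi_prop = self.draw_slab(self.P)
        lm_slab = self.log_marginal(phi_prop, c)

        # 0 -> 1 : slab proposal density cancels against the prior slab
        log_acc = np.where(
            Z,
            (lm_one - lm_cur) - logit_pi,
            (lm_slab - lm_cur) + logit_pi,
        )
        accept = np.log(rng.random(self.P)) < log_acc
        newZ = np.where(accept, ~Z, Z)
        phi = np.where(accept, np.where(Z, 1.0, phi_prop), phi)
        lm_cur = np.where(accept, np.where(Z, lm_one, lm_slab), lm_cur)
        Z = newZ

        # independence refresh from the slab (Z stays 1)
        if Z.any():
            phi_p = self.draw_slab(self.P)
            lm_p = self.log_marginal(phi_p, c)
            acc = Z & (np.log(rng.random(self.P)) < lm_p - lm_cur)
            phi = np.where(acc, phi_p, phi)
            lm_cur = np.where(acc, lm_p, lm_cur)

            # multiplicative random walk on phi - phi_min
            step = np.exp(rng.normal(0.0, 0.25, size=self.P))
            phi_w = cfg.phi_min + (phi - cfg.phi_min) * step
            lm_w = self.log_marginal(phi_w, c)
            with np.errstate(invalid="ignore"):
                log_acc = (
                    lm_w - lm_cur
                    + self.log_slab_pdf(phi_w) - self.log_slab_pdf(phi)
                    + np.log(step)  # Jacobian of multiplicative proposal
                )
            acc = Z & (np.log(rng.random(self.P)) < log_acc)
            phi = np.where(acc, phi_w, phi)
            lm_cur = np.where(acc, lm_w, lm_cur)

        state.Z, state.phi = Z, phi
        return lm_cur

    def update_theta(self, state: ChainState) -> None:
        mean = state.c * state.phi * self.mu0
        a, b = _beta_shapes(mean, self.s20)
        theta = self.rng.beta(a + self.Y, b + self.n - self.Y)
        state.theta = np.clip(theta, _THETA_FLOOR, 1 - _THETA_FLOOR)

    def _c_logpost(self, c: float, state: ChainState) -> float:
        if not 0.0 < c < 1.0:
            return -np.inf
        cfg = self.cfg
        lp = (cfg.a_c - 1) * np.log(c) + (cfg.b_c - 1) * np.log1p(-c)
        terms = self.log_theta_prior(state.theta, state.phi, c)
        s = terms.sum()
        return float(lp + s) if np.isfinite(s) else -np.inf

    def update_c(self, state: ChainState, width: float = 0.02,
                 max_steps: int = 30) -> None:
        """Univariate slice sampler on (0, 1) with stepping out."""
        rng = self.rng
        x0 = state.c
        f0 = self._c_logpost(x0, state)
        logy = f0 + np.log(rng.random())
        lo = x0 - width * rng.random()
        hi = lo + width
        steps = 0
        while lo > 0.0 and steps < max_steps and \
                self._c_logpost(lo, state) > logy:
            lo -= width
            steps += 1
        steps = 0
        while hi < 1.0 and steps < max_steps and \
                self._c_logpost(hi, state) > logy:
            hi += width
            steps += 1
        lo, hi = max(lo, 0.0), min(hi, 1.0)
        while True:
            x1 = lo + (hi - lo) * rng.random()
            if self._c_logpost(x1, state) > logy:
                state.c = x1
                return
            if x1 < x0:
                lo = x1
            else:
                hi = x1
            if hi - lo < 1e-12:
                state.c = x0
                return

    def update_pi(self, state: ChainState) -> None:
        cfg = self.cfg
        k = int(state.Z.sum())
        state.pi = float(
            self.rng.beta(cfg.a_pi + k, cfg.b_pi + self.P - k)
        )


def _run_chain(smp: "_Sampler", state: ChainState, config: BeerConfig,
               lm_cur: np.ndarray):
    """One full Gibbs run; returns ergodic means.

    ``phi_hat`` is the mean of the fold change over iterations with
    Z = 1 (1.0 for peptides never sampled as enriched).
    """
    P = smp.P
    z_sum = np.zeros(P)
    phi_sum = np.zeros(P)
    phi_n = np.zeros(P)
    c_sum = 0.0
    pi_sum = 0.0
    total = config.n_burn + config.n_iter
    for it in range(total):
        lm_cur = smp.update_z_phi(state, lm_cur)
        smp.update_theta(state)
        c_before = state.c
        smp.update_c(state)
        if state.c != c_before:
            lm_cur = smp.log_marginal(state.phi, state.c)
        smp.update_pi(state)
        if it >= config.n_burn:
            z_sum += state.Z
            phi_sum[state.Z] += state.phi[state.Z]
            phi_n += state.Z
            c_sum += state.c
            pi_sum += state.pi
    k = float(config.n_iter)
    post_prob = z_sum / k
    phi_hat = np.where(phi_n > 0, phi_sum / np.maximum(phi_n, 1), 1.0)
    return post_prob, phi_hat, c_sum / k, pi_sum / k


def run_mcmc(
    m: PeptideCountMatrix,
    prior: BeadsPrior,
    config: BeerConfig,
    serum: str,
    excluded: pd.Series | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler for one serum sample and summarize.

    Expects the super-enriched pre-filter to have been applied already
    (``excluded`` carries those peptides' initial fold-change estimates)
    and the prior to be guarded (``a0 >= 1``).  Chains are fully
    reproducible from ``config.seed``.
    """
    prior = prior.reindex(m.peptide_ids)
    rng = np.random.default_rng(config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        state = initialize_chain(m, prior, serum)
    Y = m.counts[serum].to_numpy(dtype=float)
    n = float(m.library_sizes[serum])
    smp = _Sampler(Y, n, prior.mu0, prior.sigma2_0, config, rng)

    lm_cur = smp.log_marginal(state.phi, state.c)
    if not np.all(np.isfinite(lm_cur)):
        bad = m.peptide_ids[~np.isfinite(lm_cur)]
        raise RuntimeError(
            f"non-finite marginal at initialization for {list(bad)[:5]}"
        )

    post_prob, phi_hat, c_hat, pi_hat = _run_chain(smp, state, config, lm_cur)
    tab = pd.DataFrame(
        {
            "post_prob": post_prob,
            "phi_hat": phi_hat,
            "excluded": False,
        },
        index=m.peptide_ids,
    )
    if excluded is not None and len(excluded):
        extra = pd.DataFrame(
            {
                "post_prob": 1.0,
                "phi_hat": excluded.to_numpy(dtype=float),
                "excluded": True,
            },
            index=excluded.index,
        )
        tab = pd.concat([tab, extra])
    return PosteriorSummary(
        table=tab,
        sample_id=serum,
        c_hat=c_hat,
        pi_hat=pi_hat,
        n_iter=config.n_iter,
        n_burn=config.n_burn,
        seed=config.seed,
    )
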