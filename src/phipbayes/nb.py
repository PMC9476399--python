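"""Negative-binomial comparator: dispersion estimation and exact test.

The comparator treats each peptide's read counts as negative binomial to
absorb the larger-than-binomial variability between samples.  A plate-wide
(common) dispersion is estimated by maximizing the conditional likelihood
given per-peptide totals; per-peptide (tagwise) dispersions are obtained
by weighted-likelihood empirical Bayes, shrinking each peptide toward the
common value.  A serum sample is then compared against the beads-only
group with a conditional exact test: given the combined (library-size
adjusted) total for a peptide, the serum share follows a beta-binomial
whose shapes are the groups' inverse dispersions, and the two-sided
p-value doubles the smaller tail.  Because only read-count *enrichment*
indicates antibody reactivity, two-sided p-values are converted to
one-sided ones, and false discovery is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .phipdata import PeptideCountMatrix

# dispersions below this behave as Poisson; the conditional law is binomial
_POISSON_DISP = 1e-4
_DISP_GRID = np.logspace(-6, 1, 85)


@dataclass
class DispersionEstimate:
    """Common and tagwise squared coefficients of variation."""

    common: float
    tagwise: np.ndarray
    shrinkage_weight: float
    peptide_ids: pd.Index

    def __post_init__(self) -> None:
        self.tagwise = np.asarray(self.tagwise, dtype=float)
        if not np.all(np.isfinite(self.tagwise)) or np.any(self.tagwise < 0):
            raise ValueError("tagwise dispersions must be finite, >= 0")


@dataclass
class TestResult:
    """Per-peptide test output for one serum sample vs. the beads group."""

    table: pd.DataFrame  # columns: log_fc, p_two (+ p_one, q, called later)
    sample_id: str

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


# ----------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    m: PeptideCountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors for every sample.

    The reference defaults to the beads-only sample whose library size is
    the median among beads.  Factors are normalized to have geometric
    mean 1.
    """
    if reference is None:
        beads = m.beads_ids or list(m.sample_ids)
        libs = m.library_sizes[beads]
        reference = (libs - libs.median()).abs().idxmin()
    n = m.library_sizes.astype(float)
    p_ref = m.counts[reference].to_numpy(float) / n[reference]
    factors = {}
    for s in m.sample_ids:
        if s == reference:
            factors[s] = 1.0
            continue
        y = m.counts[s].to_numpy(float)
        yr = m.counts[reference].to_numpy(float)
        ok = (y > 0) & (yr > 0)
        if ok.sum() < 10:
            factors[s] = 1.0
            continue
        p = y[ok] / n[s]
        pr = p_ref[ok]
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        # asymptotic inverse variance of M (delta method)
        w = (n[s] - y[ok]) / (n[s] * y[ok]) + (
            n[reference] - yr[ok]
        ) / (n[reference] * yr[ok])
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if keep.sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = float(
                2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
            )
    f = pd.Series(factors).reindex(m.sample_ids)
    return f / np.exp(np.log(f).mean())


# ----------------------------------------------------------------------
# dispersion estimation


def _cond_loglik_grid(y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-peptide conditional NB log-likelihood on a dispersion grid.

    ``y`` is a peptides x samples matrix of (equalized) counts from one
    group.  For equal library sizes the distribution of the counts given
    their total is free of the mean, giving a likelihood for the
    dispersion alone: with r = 1/dispersion,

        l(r) = sum_k lgamma(y_k + r) - K lgamma(r)
               - lgamma(z + K r) + lgamma(K r),  z = sum_k y_k.

    Returns a peptides x grid matrix (constants in the data dropped).
    """
    y = np.asarray(y, dtype=float)
    n_samp = y.shape[1]
    z = y.sum(axis=1)
    r = 1.0 / grid  # (G,)
    ll = np.zeros((y.shape[0], grid.size))
    for g, rg in enumerate(r):
        ll[:, g] = (
            special.gammaln(y + rg).sum(axis=1)
            - n_samp * special.gammaln(rg)
            - special.gammaln(z + n_samp * rg)
            + special.gammaln(n_samp * rg)
        )
    return ll


def _equalized_counts(m: PeptideCountMatrix, samples: list[str]) -> np.ndarray:
    """Counts linearly scaled to the geometric-mean library size."""
    y = m.counts[samples].to_numpy(float)
    n = m.library_sizes[samples].to_numpy(float)
    target = np.exp(np.mean(np.log(n)))
    return y * (target / n)


def _interp_argmax(ll: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-row argmax on the grid, refined by a log-parabola vertex."""
    k = np.argmax(ll, axis=1)
    x = np.log(grid)
    out = grid[k].astype(float)
    interior = (k > 0) & (k < grid.size - 1)
    idx = np.nonzero(interior)[0]
    if idx.size:
        km = k[idx]
        y0 = ll[idx, km - 1]
        y1 = ll[idx, km]
        y2 = ll[idx, km + 1]
        x0, x1, x2 = x[km - 1], x[km], x[km + 1]
        # three-point parabola vertex in log-dispersion
        num = (y0 - y1) * (x1 - x2) ** 2 - (y1 - y2) * (x1 - x0) ** 2
        den = (y0 - y1) * (x1 - x2) + (y1 - y2) * (x1 - x0)
        with np.errstate(divide="ignore", invalid="ignore"):
            xv = x1 - 0.5 * np.where(den != 0, num / den, 0.0)
        ok = np.isfinite(xv) & (xv >= x0) & (xv <= x2)
        out[idx[ok]] = np.exp(xv[ok])
    return out


def estimate_dispersions(
    m: PeptideCountMatrix,
    groups,
    shrinkage_weight: float = 10.0,
) -> DispersionEstimate:
    """Common and tagwise NB dispersions from within-group variability.

    Parameters
    ----------
    m : PeptideCountMatrix
    groups : mapping of sample id -> group label
        Only the listed samples are used; every group needs >= 2 samples.
    shrinkage_weight : float
        Prior degrees of freedom of the weighted-likelihood moderation;
        each peptide's likelihood is combined with ``shrinkage_weight``
        copies of the plate-average likelihood, so tagwise values shrink
        toward the common dispersion (and equal it in the limit).
    """
    groups = pd.Series(dict(groups))
    ll = np.zeros((m.n_peptides, _DISP_GRID.size))
    for label in groups.unique():
        samples = list(groups.index[groups == label])
        if len(samples) < 2:
            raise ValueError(
                f"group {label!r} has {len(samples)} sample(s); need >= 2"
            )
        ll += _cond_loglik_grid(_equalized_counts(m, samples), _DISP_GRID)
    lbar = ll.mean(axis=0)
    common = float(_interp_argmax(lbar[None, :], _DISP_GRID)[0])
    wl = ll + shrinkage_weight * lbar[None, :]
    tagwise = _interp_argmax(wl, _DISP_GRID)
    return DispersionEstimate(common, tagwise, shrinkage_weight, m.peptide_ids)


# ----------------------------------------------------------------------
# exact test


def nb_exact_test(
    m: PeptideCountMatrix,
    disp: DispersionEstimate,
    serum: str,
    norm_factors: pd.Series | None = None,
) -> TestResult:
    """Conditional exact test of one serum sample against the beads group.

    Counts are scaled to a common effective library size (library size
    times TMM factor).  Under the null of a shared negative-binomial mean
    with tagwise dispersion tau, the serum pseudo-count given the combined
    total z is beta-binomial(z, 1/tau, N/tau) for N beads samples; the
    two-sided p-value is twice the smaller tail (capped at 1).  At
    dispersion ~0 this reduces to the binomial (Poisson-limit) exact test.
    """
    beads = m.beads_ids
    if len(beads) < 2:
        raise ValueError("need at least 2 beads-only samples")
    if norm_factors is None:
        norm_factors = tmm_factors(m)
    samples = beads + [serum]
    eff = m.library_sizes[samples].astype(float) * norm_factors[samples]
    target = float(np.exp(np.mean(np.log(eff))))
    pseudo = m.counts[samples].to_numpy(float) * (
        target / eff.to_numpy()
    )
    y_beads = pseudo[:, :-1]
    y_serum = pseudo[:, -1]
    n_beads = len(beads)

    z = np.rint(y_beads.sum(axis=1) + y_serum)
    yb = np.minimum(np.rint(y_serum), z)
    tau = np.maximum(disp.tagwise, 0.0)

    p_two = np.ones(m.n_peptides)
    nonzero = z > 0
    pois = nonzero & (tau < _POISSON_DISP)
    overd = nonzero & ~pois
    if pois.any():
        lower = stats.binom.cdf(yb[pois], z[pois], 1.0 / (n_beads + 1))
        upper = stats.binom.sf(yb[pois] - 1, z[pois], 1.0 / (n_beads + 1))
        p_two[pois] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    if overd.any():
        r = 1.0 / tau[overd]
        lower = stats.betabinom.cdf(yb[overd], z[overd], r, n_beads * r)
        upper = stats.betabinom.sf(yb[overd] - 1, z[overd], r, n_beads * r)
        p_two[overd] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

    prior = 0.5
    log_fc = np.log2(
        (y_serum + prior) / (y_beads.mean(axis=1) + prior)
    )
    log_fc[~nonzero] = 0.0
    tab = pd.DataFrame(
        {"log_fc": log_fc, "p_two": np.clip(p_two, 0.0, 1.0)},
        index=m.peptide_ids,
    )
    return TestResult(tab, serum)


def to_one_sided(r: TestResult) -> TestResult:
    """Convert two-sided p-values to one-sided (enrichment) p-values.

    The alternative to no reactivity (fold change 1) is enrichment, so the
    two-sided p is halved when the fold change points up and reflected
    (``1 - p/2``) when it points down or is flat.
    """
    tab = r.table.copy()
    up = tab["log_fc"].to_numpy() > 0
    p2 = tab["p_two"].to_numpy()
    tab["p_one"] = np.where(up, p2 / 2.0, 1.0 - p2 / 2.0)
    return TestResult(tab, r.sample_id)


def bh_adjust(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q, called)`` with ``called = q <= alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    called, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def nb_test(
    m: PeptideCountMatrix,
    serum: str,
    alpha: float = 0.05,
    shrinkage_weight: float = 10.0,
    disp: DispersionEstimate | None = None,
) -> TestResult:
    """Full comparator pipeline for one serum sample.

    Estimates tagwise dispersions from the beads-only columns, runs the
    conditional exact test, converts to one-sided p-values and applies
    Benjamini-Hochberg at ``alpha``.
    """
    if disp is None:
        disp = estimate_dispersions(
            m, {s: "beads" for s in m.beads_ids}, shrinkage_weight
        )
    res = to_one_sided(nb_exact_test(m, disp, serum))
    q, called = bh_adjust(res.table["p_one"].to_numpy(), alpha)
    res.table["q"] = q
    res.table["called"] = called
    return res
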