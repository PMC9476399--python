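"""Beads-only Beta prior estimation.

Each peptide's probability of pulling a read in a mock IP is modelled as
Beta(:math:`a_{i0}`, :math:`b_{i0}`).  Three routes estimate those shapes
from the observed beads-only proportions :math:`\\hat\\theta_{ij} =
Y_{ij}/n_j`:

* method of moments (``mom``) — equate the sample mean/variance of the
  proportions to the Beta moments;
* constrained maximum likelihood (``mle``) — per-peptide Beta likelihood,
  box-constrained quasi-Newton;
* dispersion-derived (``edger``) — the recommended default: replace the
  noisy per-peptide sample variance by :math:`\\tau_i \\hat\\theta_{i0}^2`,
  where :math:`\\tau_i` is the empirical-Bayes tagwise dispersion (squared
  coefficient of variation) shrunk toward a plate-wide value, so strength
  is borrowed across peptides.

Because a Beta shape ``a`` below 1 puts unbounded density at 0 and is
numerically fragile for samplers, every route ends with a guard that
raises ``a`` to at least 1 and recomputes ``b`` so the mean is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .phipdata import PeptideCountMatrix

_EPS_PROP = 1e-10  # clip proportions away from the Beta boundary


class InfeasibleMomentsError(ValueError):
    """Variance at or above mu*(1-mu): no Beta distribution has it."""


def beta_shapes_from_moments(mu, sigma2):
    """Beta shapes (a, b) with the given mean and variance.

    ``a = mu^2 (1 - mu) / sigma2 - mu`` and ``b = a (1/mu - 1)``.
    Raises :class:`InfeasibleMomentsError` when ``sigma2 >= mu (1 - mu)``,
    where the implied ``a`` would be non-positive.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    if np.any(sigma2 >= mu * (1 - mu)):
        raise InfeasibleMomentsError("sigma2 >= mu*(1-mu)")
    a = mu**2 * (1 - mu) / sigma2 - mu
    b = a * (1 / mu - 1)
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def beta_moments(a, b):
    """Mean and variance of Beta(a, b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("shapes must be positive")
    s = a + b
    mu = a / s
    sigma2 = a * b / (s**2 * (s + 1))
    if mu.ndim == 0:
        return float(mu), float(sigma2)
    return mu, sigma2


def apply_guard(a, b):
    """Raise ``a`` to at least 1, recomputing ``b`` to preserve the mean.

    With the mean :math:`\\mu = a/(a+b)` held fixed, ``a < 1`` is replaced
    by 1 and ``b`` by :math:`1 \\cdot (1/\\mu - 1)`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mu = a / (a + b)
    low = a < 1.0
    a_out = np.where(low, 1.0, a)
    b_out = np.where(low, 1.0 * (1.0 / mu - 1.0), b)
    if a_out.ndim == 0:
        return float(a_out), float(b_out)
    return a_out, b_out


@dataclass
class BeadsPrior:
    """Per-peptide background Beta parameters, aligned to a peptide index."""

    table: pd.DataFrame  # columns: mu0, sigma2_0, a0, b0
    method: str

    def __post_init__(self) -> None:
        need = {"mu0", "sigma2_0", "a0", "b0"}
        if not need <= set(self.table.columns):
            raise ValueError(f"prior table needs columns {sorted(need)}")

    @property
    def peptide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def mu0(self) -> np.ndarray:
        return self.table["mu0"].to_numpy()

    @property
    def sigma2_0(self) -> np.ndarray:
        return self.table["sigma2_0"].to_numpy()

    @property
    def a0(self) -> np.ndarray:
        return self.table["a0"].to_numpy()

    @property
    def b0(self) -> np.ndarray:
        return self.table["b0"].to_numpy()

    def reindex(self, peptide_ids) -> "BeadsPrior":
        missing = pd.Index(peptide_ids).difference(self.table.index)
        if len(missing):
            raise KeyError(f"prior missing peptides: {list(missing)[:5]}")
        return BeadsPrior(self.table.loc[peptide_ids].copy(), self.method)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "peptide_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_shapes(cls, peptide_ids, a0, b0, method: str) -> "BeadsPrior":
        """Build a prior from (guarded) shapes; moments are derived."""
        mu, s2 = beta_moments(np.asarray(a0, float), np.asarray(b0, float))
        tab = pd.DataFrame(
            {"mu0": mu, "sigma2_0": s2, "a0": a0, "b0": b0},
            index=pd.Index(peptide_ids),
        )
        return cls(tab, method)


# ----------------------------------------------------------------------
# shared helpers


def _beads_proportions(m: PeptideCountMatrix) -> np.ndarray:
    beads = m.beads_ids
    if len(beads) < 2:
        raise ValueError("need at least 2 beads-only samples")
    y = m.counts[beads].to_numpy(dtype=float)
    n = m.library_sizes[beads].to_numpy(dtype=float)
    return y / n


def _fallback_moments(mu: np.ndarray, feasible_var: np.ndarray,
                      mean_lib: float) -> tuple[np.ndarray, np.ndarray]:
    """Repair degenerate per-peptide moments.

    All-zero peptides get half a pseudo-read of mean (``mu0 =
    1/(2 n̄)``); zero or infeasible variances get a binomial-scale
    variance ``mu (1-mu) / (n̄ + 1)``, i.e. no overdispersion is
    invented for peptides whose beads replicates happen to agree.
    """
    mu = mu.copy()
    var = feasible_var.copy()
    mu[mu <= 0] = 1.0 / (2.0 * mean_lib)
    mu = np.clip(mu, _EPS_PROP, 1 - _EPS_PROP)
    # (mu * 1e-9)**2 catches variances that are zero up to round-off
    bad = (
        ~np.isfinite(var)
        | (var <= (mu * 1e-9) ** 2)
        | (var >= mu * (1 - mu))
    )
    var[bad] = (mu[bad] * (1 - mu[bad])) / (mean_lib + 1.0)
    return mu, var


def _prior_from_moments(m: PeptideCountMatrix, mu, var, method: str
                        ) -> BeadsPrior:
    mean_lib = float(m.library_sizes[m.beads_ids].mean())
    mu, var = _fallback_moments(np.asarray(mu, float),
                                np.asarray(var, float), mean_lib)
    a, b = beta_shapes_from_moments(mu, var)
    a, b = apply_guard(a, b)
    return BeadsPrior.from_shapes(m.peptide_ids, a, b, method)


# ----------------------------------------------------------------------
# estimators


def estimate_mom(m: PeptideCountMatrix) -> BeadsPrior:
    """Method-of-moments beads prior from per-peptide proportion moments."""
    theta = _beads_proportions(m)
    mu = theta.mean(axis=1)
    var = theta.var(axis=1, ddof=1)
    return _prior_from_moments(m, mu, var, "mom")


def _beta_negloglik(params: np.ndarray, x: np.ndarray) -> float:
    a, b = params
    return -float(
        np.sum((a - 1) * np.log(x) + (b - 1) * np.log1p(-x))
        - x.size * special.betaln(a, b)
    )


def estimate_mle(m: PeptideCountMatrix) -> BeadsPrior:
    """Per-peptide Beta maximum likelihood on the beads proportions.

    Box-constrained L-BFGS-B started at the method-of-moments solution;
    peptides where the optimizer fails or the data are degenerate keep
    their MOM values.  Proportions are clipped to ``[1e-10, 1 - 1e-10]``
    since the Beta likelihood is undefined at the boundary.
    """
    theta = np.clip(_beads_proportions(m), _EPS_PROP, 1 - _EPS_PROP)
    mom = estimate_mom(m)
    a_out = mom.a0.copy()
    b_out = mom.b0.copy()
    bounds = [(1e-6, 1e6), (1e-6, 1e6)]
    for i in range(theta.shape[0]):
        x = theta[i]
        if np.allclose(x, x[0]):
            continue  # degenerate: likelihood unbounded, keep MOM fallback
        x0 = np.array([mom.a0[i], mom.b0[i]])
        res = optimize.minimize(
            _beta_negloglik, x0, args=(x,), method="L-BFGS-B", bounds=bounds
        )
        if res.success and np.all(np.isfinite(res.x)):
            a_out[i], b_out[i] = res.x
    a_out, b_out = apply_guard(a_out, b_out)
    return BeadsPrior.from_shapes(m.peptide_ids, a_out, b_out, "mle")


def estimate_dispersion_derived(
    m: PeptideCountMatrix, disp
) -> BeadsPrior:
    """Beads prior from empirical-Bayes tagwise dispersions (default route).

    The per-peptide variance of the read-pull probability is taken as
    ``sigma2_i0 = tau_i * theta_i0^2`` with ``tau_i`` the tagwise squared
    coefficient of variation, so small plates still get stable variance
    estimates by borrowing strength across peptides.

    Parameters
    ----------
    m : PeptideCountMatrix
    disp : DispersionEstimate
        From :func:`phipbayes.nb.estimate_dispersions` on the beads-only
        columns; its tagwise series must cover every peptide of ``m``.
    """
    tag = pd.Series(disp.tagwise, index=disp.peptide_ids)
    missing = m.peptide_ids.difference(tag.index)
    if len(missing):
        raise KeyError(f"dispersion missing peptides: {list(missing)[:5]}")
    tau = tag.loc[m.peptide_ids].to_numpy(dtype=float)
    theta = _beads_proportions(m)
    mu = theta.mean(axis=1)
    var = tau * mu**2
    return _prior_from_moments(m, mu, var, "edger")


def estimate_prior(m: PeptideCountMatrix, method: str = "edger") -> BeadsPrior:
    """Dispatch on ``method`` in {"mom", "mle", "edger"}."""
    if method == "mom":
        return estimate_mom(m)
    if method == "mle":
        return estimate_mle(m)
    if method == "edger":
        from .nb import estimate_dispersions

        beads = m.beads_ids
        disp = estimate_dispersions(m, {s: "beads" for s in beads})
        return estimate_dispersion_derived(m, disp)
    raise ValueError(f"unknown prior method {method!r}")
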