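"""Evaluation machinery: ROC/PR curves, FDR-matched cutoffs, power
regression, round-robin false-positive counts, and ranked-list
concordance.

Curves from several simulated datasets are linearly interpolated onto a
shared support grid so they can be averaged point-wise; areas under the
interpolated ROC curves use the trapezoid rule.  For a fair power
comparison against p-value-based FDR control, posterior-probability
cutoffs are chosen per dataset so that the false-discovery proportion
among calls matches a target level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

SUPPORT = np.linspace(0.0, 1.0, 501)


@dataclass
class CurveSet:
    """Interpolated per-dataset curves on a shared x grid, plus means."""

    kind: str  # "roc" or "pr"
    support: np.ndarray
    curves: np.ndarray  # datasets x support
    mean_curve: np.ndarray
    auc: np.ndarray  # per dataset
    mean_auc: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.curves.T,
            columns=[f"dataset_{i}" for i in range(self.curves.shape[0])],
        )
        df.insert(0, "support", self.support)
        df["mean"] = self.mean_curve
        return df


def _rank_scores(scores: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Stable ordering: score descending, id ascending for ties."""
    order = np.lexsort((ids, -scores))
    return order


def _one_roc(scores, truth, support):
    fpr, tpr, _ = roc_curve(truth, scores)
    # roc_curve returns monotone fpr starting at 0
    return np.interp(support, fpr, tpr)


def _one_pr(scores, truth, support):
    prec, rec, _ = precision_recall_curve(truth, scores)
    # returned in decreasing recall; flip and anchor at (0 recall, PPV 1)
    rec = rec[::-1]
    prec = prec[::-1]
    if rec[0] > 0:
        rec = np.concatenate([[0.0], rec])
        prec = np.concatenate([[1.0], prec])
    # at tied recall keep the best attainable precision (highest threshold)
    rec, first = np.unique(rec, return_index=True)
    prec = prec[first]
    return np.interp(support, rec, prec)


def roc_pr_curves(
    scores: list[np.ndarray],
    truth: list[np.ndarray],
    support: np.ndarray = SUPPORT,
) -> tuple[CurveSet, CurveSet]:
    """Interpolated, averaged ROC and PR curves over datasets.

    ``scores`` and ``truth`` are parallel lists, one entry per dataset;
    scores must orient so that larger means more enriched (posterior
    probability, or one minus the one-sided p-value for the exact test).
    Datasets without any enriched peptide are skipped.  AUCs come from
    the trapezoid rule on the interpolated points.
    """
    roc_rows, pr_rows = [], []
    for s, t in zip(scores, truth):
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=bool)
        if t.sum() == 0 or (~t).sum() == 0:
            continue
        roc_rows.append(_one_roc(s, t, support))
        pr_rows.append(_one_pr(s, t, support))
    if not roc_rows:
        raise ValueError("no dataset had both enriched and null peptides")
    roc = np.vstack(roc_rows)
    pr = np.vstack(pr_rows)
    roc_auc = np.trapezoid(roc, support, axis=1)
    pr_auc = np.trapezoid(pr, support, axis=1)
    roc_set = CurveSet(
        "roc", support, roc, roc.mean(axis=0), roc_auc,
        float(roc_auc.mean()),
    )
    pr_set = CurveSet(
        "pr", support, pr, pr.mean(axis=0), pr_auc, float(pr_auc.mean()),
    )
    return roc_set, pr_set


def fdr_matched_cutoff(
    post_prob: np.ndarray, truth: np.ndarray, target: float = 0.05
) -> float:
    """Smallest score cutoff with false-discovery proportion <= target.

    Calls are ``post_prob > cutoff``.  Scanning thresholds from the top
    score down, the largest admissible call set whose realized FDP stays
    at or below ``target`` determines the cutoff; 1 is returned when
    even the single best call is a false positive (or there are no true
    positives at all).
    """
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    post_prob = np.asarray(post_prob, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.sum() == 0:
        import warnings

        warnings.warn("no true positives; returning cutoff 1", stacklevel=2)
        return 1.0
    order = np.argsort(-post_prob, kind="stable")
    s = post_prob[order]
    t = truth[order]
    fp = np.cumsum(~t)
    k = np.arange(1, s.size + 1)
    fdp = fp / k
    # a cutoff can only sit between distinct score values
    boundary = np.r_[s[1:] != s[:-1], True]
    ok = (fdp <= target) & boundary
    if not ok.any():
        return 1.0
    last = np.nonzero(ok)[0][-1]
    return float(s[last + 1]) if last + 1 < s.size else 0.0


def power_curve(detected, fc):
    """Logistic model of detection probability against log2 fold change.

    Returns ``(model, fc50, separated)`` where ``fc50`` is the fold
    change at 50% detection probability.  Under complete separation the
    boundary between detected and missed fold changes is reported with
    ``separated=True``; a flat (slope ~ 0) fit returns ``fc50 = nan``.
    """
    import statsmodels.api as sm

    detected = np.asarray(detected, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if detected.sum() < 2 or (1 - detected).sum() < 2:
        raise ValueError("need >= 2 detected and >= 2 undetected peptides")
    x = np.log2(fc)
    hi_missed = x[detected == 0].max()
    lo_found = x[detected == 1].min()
    if lo_found > hi_missed:  # complete separation
        return None, float(2 ** ((lo_found + hi_missed) / 2)), True
    X = sm.add_constant(x)
    model = sm.GLM(detected, X, family=sm.families.Binomial()).fit()
    b0, b1 = model.params
    if abs(b1) < 1e-8:
        return model, float("nan"), False
    return model, float(2 ** (-b0 / b1)), False


def topk_concordance(rank_a, rank_b, k: int) -> float:
    """Fraction of the top-k peptides shared between two ranked lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    a = list(rank_a)[:k]
    b = list(rank_b)[:k]
    if len(a) < k or len(b) < k:
        raise ValueError("k exceeds a list length")
    return len(set(a) & set(b)) / k


def rank_peptides(scores: pd.Series) -> list[str]:
    """Peptide ids sorted by score descending, ties broken by id."""
    df = pd.DataFrame({"s": scores})
    df = df.sort_index().sort_values("s", ascending=False, kind="stable")
    return list(df.index)


def round_robin_fp(
    m,
    method: str = "beer",
    config=None,
    alpha: float = 0.05,
    cutoff: float = 0.5,
    prior_method: str = "edger",
) -> pd.Series:
    """False-positive counts from running each mock IP as a sample.

    Every beads-only sample is held out in turn, relabelled serum, and
    analyzed against the remaining beads; any enrichment call on it is a
    false positive.  ``method`` selects the Bayesian model (calls at
    posterior probability > ``cutoff``) or the exact test (calls at
    Benjamini-Hochberg FDR ``alpha`` on one-sided p-values).
    """
    from .phipdata import leave_one_beads_out
    from .workflows import run_beer, run_nb
    from .model import call_enriched

    beads = m.beads_ids
    if len(beads) < 3:
        raise ValueError("round-robin needs at least 3 beads-only samples")
    out = {}
    for held in beads:
        sub = leave_one_beads_out(m, held)
        if method == "beer":
            summ = run_beer(
                sub, held, config=config, prior_method=prior_method
            )
            out[held] = int(call_enriched(summ, cutoff).sum())
        elif method == "nb":
            res = run_nb(sub, held, alpha=alpha)
            out[held] = int(res.table["called"].sum())
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.Series(out, name="false_positives")
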