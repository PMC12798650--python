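"""Significance testing of Granger-causality values.

A GC value compares nested regressions, so its null distribution is handled
with the classical F test for nested linear models.  Families of directed
pairs are corrected with Bonferroni or the Benjamini-Hochberg step-up FDR
procedure; cross-trial aggregation reports mean/std GC and the fraction of
trials in which each connection is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificanceReport",
    "TrialAggregate",
    "gc_f_test",
    "bonferroni",
    "fdr_bh",
    "significance_masks",
    "aggregate_trials",
    "CORRECTIONS",
]

CORRECTIONS = ("none", "bonferroni", "fdr_bh")


@dataclass
class SignificanceReport:
    pvals: np.ndarray
    alpha: float
    correction: str
    mask: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.pvals = np.asarray(self.pvals, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class TrialAggregate:
    """Element-wise summary over repeated trials of one scenario."""

    mean: np.ndarray
    std: np.ndarray
    frac_significant: dict[str, np.ndarray]
    n_trials: int
    mode: str
    order: int
    single_trial: bool = False
    meta: dict = field(default_factory=dict)


def gc_f_test(rss_r: float, rss_u: float, q: int, dof_u: int) -> tuple[float, float]:
    """F test of a nested regression pair.

    ``rss_r``/``rss_u`` are restricted/unrestricted residual sums of squares,
    ``q`` the number of added regressors, ``dof_u`` the residual degrees of
    freedom of the unrestricted model.  Returns ``(F, p)`` with ``p`` the
    upper tail of F(q, dof_u).
    """
    if q < 1 or dof_u < 1:
        raise ValueError(f"invalid degrees of freedom: q={q}, dof_u={dof_u}")
    if not (rss_r >= rss_u > 0):
        raise ValueError(f"need rss_r >= rss_u > 0, got rss_r={rss_r}, rss_u={rss_u}")
    F = ((rss_r - rss_u) / q) / (rss_u / dof_u)
    p = float(stats.f.sf(F, q, dof_u))
    return float(F), p


def _flat(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(pvals, alpha: float = 0.05, n_tests: int | None = None) -> SignificanceReport:
    """Family-wise control: significant if ``p <= alpha / n_tests``.

    Thresholds are applied non-strictly throughout the module so that the
    rejection-set nesting (Bonferroni within FDR-BH within uncorrected)
    holds even at exact threshold boundaries; for continuous test
    statistics the boundary has probability zero.
    """
    p = _flat(pvals)
    n = int(n_tests) if n_tests is not None else p.size
    if n < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n
    return SignificanceReport(
        pvals=p, alpha=alpha, correction="bonferroni", mask=p <= thr,
        thresholds=np.full_like(p, thr),
    )


def fdr_bh(pvals, alpha: float = 0.05) -> SignificanceReport:
    """Benjamini-Hochberg step-up false-discovery-rate control.

    Rejects every p at or below p_(k), where k is the largest rank with
    p_(k) <= (k/n) alpha.
    """
    p = _flat(pvals)
    flat = p.ravel()
    mask, _, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")[:4]
    n = flat.size
    order = np.argsort(flat, kind="stable")
    thresholds = np.empty_like(flat)
    thresholds[order] = (np.arange(1, n + 1) / n) * alpha
    return SignificanceReport(
        pvals=p, alpha=alpha, correction="fdr_bh",
        mask=mask.reshape(p.shape), thresholds=thresholds.reshape(p.shape),
    )


def significance_masks(pvals, alpha: float = 0.05, corrections=CORRECTIONS, n_tests: int | None = None) -> dict[str, np.ndarray]:
    """Boolean masks of one p-value family under each requested correction.

    ``n_tests`` overrides the family size (e.g. the number of valid
    off-diagonal entries when ``pvals`` is a matrix padded with NaN on the
    diagonal).
    """
    p = np.asarray(pvals, dtype=float)
    valid = np.isfinite(p)
    n = int(valid.sum()) if n_tests is None else n_tests
    out: dict[str, np.ndarray] = {}
    for corr in corrections:
        mask = np.zeros(p.shape, dtype=bool)
        if corr == "none":
            mask[valid] = p[valid] <= alpha
        elif corr == "bonferroni":
            mask[valid] = bonferroni(p[valid], alpha, n_tests=n).mask
        elif corr == "fdr_bh":
            mask[valid] = fdr_bh(p[valid], alpha).mask
        else:
            raise ValueError(f"unknown correction {corr!r}")
        out[corr] = mask
    return out


def aggregate_trials(results, alpha: float = 0.05, corrections=CORRECTIONS) -> TrialAggregate:
    """Mean/std GC and per-correction significant fractions over trials.

    All results must share shape, estimation mode and model order.  With a
    single trial the std is reported as zero and flagged.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    ref = results[0]
    for r in results[1:]:
        if r.gc.shape != ref.gc.shape or r.mode != ref.mode or r.order != ref.order:
            raise ValueError("heterogeneous GCResult inputs (shape/mode/order differ)")
    gc = np.stack([r.gc for r in results])
    n = len(results)
    mean = gc.mean(axis=0)
    std = gc.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    frac = {}
    for corr in corrections:
        masks = np.stack(
            [significance_masks(r.pval, alpha=alpha, corrections=(corr,))[corr] for r in results]
        )
        frac[corr] = masks.mean(axis=0)
    return TrialAggregate(
        mean=mean, std=std, frac_significant=frac, n_trials=n,
        mode=ref.mode, order=ref.order, single_trial=(n == 1),
    )
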