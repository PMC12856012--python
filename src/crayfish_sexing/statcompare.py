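"""Paired statistical comparison of classifiers on a shared test set.

Two tests operate on per-sample correctness (0/1) of two models against
the same truth vector:

* Wilcoxon signed-rank on the correctness differences d_i in {-1, 0, +1}:
  zeros dropped, midranks for ties, W = min(positive-rank sum,
  negative-rank sum). Because every nonzero |d_i| is 1, the ranks are
  fully tied; the two-sided p-value comes from an exact
  dynamic-programming enumeration of the signed-rank distribution when at
  most 25 nonzero differences remain, else from the tie-corrected normal
  approximation.
* McNemar with continuity correction on the discordant counts:
  chi2 = (|n10 - n01| - 1)^2 / (n10 + n01), one degree of freedom. The
  printed continuity-corrected form is used verbatim, including when
  |n10 - n01| < 1.

Significance is declared at p < alpha (default 0.05) and annotated with
the model whose accuracy is higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedPredictions",
    "ContingencyCounts",
    "TestOutcome",
    "wilcoxon_paired",
    "mcnemar",
    "significance_matrix",
]

EXACT_MAX_N = 25  # largest nonzero-difference count for the exact null


@dataclass
class PairedPredictions:
    truth: np.ndarray
    pred_a: np.ndarray
    pred_b: np.ndarray

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth)
        self.pred_a = np.asarray(self.pred_a)
        self.pred_b = np.asarray(self.pred_b)
        if not (len(self.truth) == len(self.pred_a) == len(self.pred_b)):
            raise ValueError("truth and both prediction vectors must align")

    def correctness(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.pred_a == self.truth).astype(int), \
               (self.pred_b == self.truth).astype(int)


@dataclass(frozen=True)
class ContingencyCounts:
    """Per-sample correctness agreement table of two models."""

    n11: int  # both correct
    n10: int  # only A correct
    n01: int  # only B correct
    n00: int  # both wrong

    @classmethod
    def from_pairs(cls, pp: PairedPredictions) -> "ContingencyCounts":
        a, b = pp.correctness()
        return cls(
            n11=int(np.sum((a == 1) & (b == 1))),
            n10=int(np.sum((a == 1) & (b == 0))),
            n01=int(np.sum((a == 0) & (b == 1))),
            n00=int(np.sum((a == 0) & (b == 0))),
        )


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    significant: bool
    better_model: str  # "A", "B" or "none"
    alpha: float = 0.05


def _better(pp: PairedPredictions) -> str:
    a, b = pp.correctness()
    if a.sum() > b.sum():
        return "A"
    if b.sum() > a.sum():
        return "B"
    return "none"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments, midranks allowed.

    Works on doubled ranks so every achievable sum is an integer;
    distribution built by polynomial convolution over the 2^m equally
    likely sign vectors.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt / 2.0
    w2 = int(round(2 * w_plus))
    lo = min(w2, total - w2)
    p = dist[: lo + 1].sum() + dist[total - lo :].sum()
    return float(min(1.0, p))


def wilcoxon_paired(pp: PairedPredictions, alpha: float = 0.05) -> TestOutcome:
    """Wilcoxon signed-rank test on per-sample correctness differences."""
    a, b = pp.correctness()
    d = a - b
    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        return TestOutcome(math.nan, 1.0, False, "none", alpha)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    w = min(w_plus, w_minus)
    if m <= EXACT_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mn = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        _, counts = np.unique(np.abs(nz), return_counts=True)
        var -= np.sum(counts**3 - counts) / 48.0
        if var == 0:
            p = 1.0
        else:
            z = (w_plus - mn) / math.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
            p = min(1.0, p)
    sig = p < alpha
    return TestOutcome(w, p, sig, _better(pp) if sig else "none", alpha)


def mcnemar(pp: PairedPredictions, alpha: float = 0.05) -> TestOutcome:
    """Continuity-corrected McNemar test on the discordant counts."""
    cc = ContingencyCounts.from_pairs(pp)
    disc = cc.n10 + cc.n01
    if disc == 0:
        return TestOutcome(math.nan, 1.0, False, "none", alpha)
    chi2 = (abs(cc.n10 - cc.n01) - 1) ** 2 / disc
    p = float(stats.chi2.sf(chi2, df=1))
    sig = p < alpha
    return TestOutcome(chi2, p, sig, _better(pp) if sig else "none", alpha)


def significance_matrix(
    model_names: list[str],
    predictions: dict[str, np.ndarray],
    truth: np.ndarray,
    test: str = "wilcoxon",
    alpha: float = 0.05,
) -> dict[tuple[str, str], TestOutcome]:
    """All-pairs comparison; one outcome per unordered model pair.

    Significant cells carry the name of the accuracy-better model in
    ``better_model`` (translated from the A/B convention).
    """
    if test not in ("wilcoxon", "mcnemar"):
        raise ValueError("test must be 'wilcoxon' or 'mcnemar'")
    truth = np.asarray(truth)
    for name in model_names:
        if len(predictions[name]) != len(truth):
            raise ValueError(f"predictions for {name!r} do not match truth length")
    run = wilcoxon_paired if test == "wilcoxon" else mcnemar
    out: dict[tuple[str, str], TestOutcome] = {}
    for i, a in enumerate(model_names):
        for b in model_names[i + 1 :]:
            pp = PairedPredictions(truth, predictions[a], predictions[b])
            res = run(pp, alpha=alpha)
            better = {"A": a, "B": b, "none": "none"}[res.better_model]
            out[(a, b)] = TestOutcome(res.statistic, res.p_value,
                                      res.significant, better, alpha)
    return out
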