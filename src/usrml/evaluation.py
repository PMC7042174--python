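"""Retrospective-screening metrics.

Two metrics drive every comparison in the pipeline:

* the **enrichment factor** at x%,

      EF_x% = (a_x / c_x) / (a_total / c_total),

  the ratio of the active fraction found in the top x% of the ranked
  library to the active fraction expected by chance (a_x actives among the
  top c_x compounds; a_total actives among c_total compounds overall), and

* the **ROC AUC**, the probability that a randomly drawn active outscores a
  randomly drawn decoy (ties counted half — the Mann-Whitney construction),
  which unlike EF does not depend on the active:decoy ratio.

Model-vs-baseline comparisons are reported as percentage ratios
(100 * EF_model / EF_baseline), and groups of results are compared with the
two-sided Wilcoxon rank-sum test (exact enumeration at small sizes, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .records import Label, ScoredMolecule

#: combined sample size up to which the Wilcoxon p-value is computed by
#: exhaustive enumeration of rank assignments
EXACT_ENUMERATION_LIMIT = 10


@dataclass
class EnrichmentResult:
    """Enrichment factor at one percentage cut of a ranked library."""

    x_percent: float
    a_x: int
    c_x: int
    a_total: int
    c_total: int
    ef: float


@dataclass
class EvaluationReport:
    """Bundle of screening metrics for one ranked library."""

    ef: Dict[float, float]
    roc_auc: float
    n_actives: int
    n_compounds: int
    improvement_ratio_percent: Optional[Dict[float, Optional[float]]] = None
    baseline_name: Optional[str] = None
    baseline_missing: bool = False
    notes: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "ef": {str(k): v for k, v in self.ef.items()},
            "roc_auc": self.roc_auc,
            "n_actives": self.n_actives,
            "n_compounds": self.n_compounds,
            "baseline_name": self.baseline_name,
            "baseline_missing": self.baseline_missing,
            "improvement_ratio_percent": (
                None
                if self.improvement_ratio_percent is None
                else {str(k): v for k, v in self.improvement_ratio_percent.items()}
            ),
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            ef={float(k): v for k, v in d["ef"].items()},
            roc_auc=d["roc_auc"],
            n_actives=d["n_actives"],
            n_compounds=d["n_compounds"],
            improvement_ratio_percent=(
                None
                if d["improvement_ratio_percent"] is None
                else {float(k): v for k, v in d["improvement_ratio_percent"].items()}
            ),
            baseline_name=d["baseline_name"],
            baseline_missing=d["baseline_missing"],
            notes=d.get("notes", {}),
        )


def enrichment_factor(
    ranked: Sequence[ScoredMolecule], x_percent: float
) -> EnrichmentResult:
    """Enrichment factor over the top x% of a ranked library.

    The cut size is ``c_x = ceil(x/100 * c_total)`` with a floor of one
    compound, so the selection is never empty even at 0.25% on small sets.
    The input must already be sorted non-increasing by score; ties at the
    boundary are resolved by the list's own (deterministic) order.
    """
    if not ranked:
        raise ValueError("ranked list must be non-empty")
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    scores = [m.score for m in ranked]
    if any(s2 > s1 for s1, s2 in zip(scores, scores[1:])):
        raise ValueError("ranked list must be sorted non-increasing by score")
    c_total = len(ranked)
    a_total = sum(1 for m in ranked if m.label == Label.ACTIVE)
    if a_total == 0:
        raise ValueError("enrichment factor undefined: no actives in list")
    c_x = max(1, math.ceil(x_percent / 100.0 * c_total))
    a_x = sum(1 for m in ranked[:c_x] if m.label == Label.ACTIVE)
    ef = (a_x / c_x) / (a_total / c_total)
    return EnrichmentResult(
        x_percent=x_percent, a_x=a_x, c_x=c_x, a_total=a_total, c_total=c_total, ef=ef
    )


def roc_auc(scored: Sequence[ScoredMolecule]) -> float:
    """Probability that a random active outscores a random decoy (ties 1/2)."""
    y = [1 if m.label == Label.ACTIVE else 0 for m in scored]
    if len(set(y)) < 2:
        raise ValueError("ROC AUC requires both actives and decoys")
    return float(roc_auc_score(y, [m.score for m in scored]))


def improvement_ratio(ef_model: float, ef_baseline: float) -> Optional[float]:
    """Model EF as a percentage of baseline EF; None when baseline is zero.

    A value of 100 means the model matched the baseline exactly.  A zero
    baseline (which genuinely occurs for hard targets) makes the ratio
    undefined; it is reported as unavailable rather than infinite.
    """
    if ef_baseline < 0 or ef_model < 0:
        raise ValueError("enrichment factors must be non-negative")
    if ef_baseline == 0:
        return None
    return 100.0 * ef_model / ef_baseline


def _rank_with_ties(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for unpaired groups.

    Returns ``(U_a, p)`` where ``U_a`` is the Mann-Whitney statistic of group
    A.  For combined sizes up to ``EXACT_ENUMERATION_LIMIT`` the p-value is
    computed by exhaustively enumerating every assignment of the pooled
    (tie-averaged) ranks to the two groups and summing the probability of
    statistics at least as far from the null mean as the observed one; this
    handles ties exactly.  Larger samples use the normal approximation with
    tie correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _rank_with_ties(pooled)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0

    n = n_a + n_b
    if n <= EXACT_ENUMERATION_LIMIT:
        mean_u = n_a * n_b / 2.0
        obs_dev = abs(u_a - mean_u)
        count = 0
        total = 0
        min_rank_sum = n_a * (n_a + 1) / 2.0
        for idx in combinations(range(n), n_a):
            u = ranks[list(idx)].sum() - min_rank_sum
            total += 1
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        _, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        p = float(p)
    return float(u_a), p


def summarize(
    ranked: Sequence[ScoredMolecule],
    ef_percentages: Sequence[float] = (1.0, 0.25),
    baseline: Optional[Sequence[ScoredMolecule]] = None,
    baseline_name: Optional[str] = None,
) -> EvaluationReport:
    """Assemble EF (at the configured percentages), AUC and baseline ratios."""
    efs = {x: enrichment_factor(ranked, x).ef for x in ef_percentages}
    auc = roc_auc(ranked)
    n_actives = sum(1 for m in ranked if m.label == Label.ACTIVE)
    report = EvaluationReport(
        ef=efs,
        roc_auc=auc,
        n_actives=n_actives,
        n_compounds=len(ranked),
        baseline_name=baseline_name,
    )
    if baseline is not None:
        base_efs = {x: enrichment_factor(baseline, x).ef for x in ef_percentages}
        report.improvement_ratio_percent = {
            x: improvement_ratio(efs[x], base_efs[x]) for x in ef_percentages
        }
    else:
        report.baseline_missing = True
    return report
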