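"""Discovery metrics against simulated ground truth.

Truth is strictly positional: a discovered SNP counts as a true positive
only if it is a causal index, so a hit in perfect LD with a causal SNP is
still a false positive.  An optional window-match mode (off by default)
credits discoveries within ``window`` positions of a causal SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimTruth

__all__ = ["MetricsReport", "score_discoveries", "aggregate_reports"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    fdr: float
    fpr: float
    f1: float
    n_datasets: int = 1

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "MetricsReport":
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        fdr = fp / (tp + fp) if (tp + fp) else 0.0
        fpr = fp / (fp + tn) if (fp + tn) else 0.0
        f1 = tp / (tp + 0.5 * (fp + fn)) if (tp + 0.5 * (fp + fn)) else 0.0
        return cls(tp=tp, fp=fp, fn=fn, tn=tn, recall=recall, fdr=fdr,
                   fpr=fpr, f1=f1)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "recall": self.recall, "fdr": self.fdr, "fpr": self.fpr,
            "f1": self.f1, "n_datasets": self.n_datasets,
        }


def score_discoveries(found, truth: SimTruth, window: int = 0) -> MetricsReport:
    """Confusion counts and rates of a discovered SNP set vs the truth.

    ``found`` is an iterable of SNP indices in [0, L).  With ``window`` > 0
    a non-causal discovery within that many positions of a causal SNP is
    forgiven (counted TP); default is the strict positional rule.
    """
    L = truth.causal_indicator.size
    found = np.asarray(sorted(set(int(f) for f in found)), dtype=int)
    if found.size and (found.min() < 0 or found.max() >= L):
        raise ValueError("discovered indices outside [0, L)")
    causal = set(truth.causal_positions.tolist())
    if window > 0:
        hit = np.array(
            [any(abs(f - c) <= window for c in causal) for f in found], dtype=bool
        ) if found.size else np.empty(0, dtype=bool)
    else:
        hit = np.isin(found, list(causal))
    tp = int(np.isin(list(causal), found).sum())  # causal SNPs recovered
    fp = int((~hit).sum())
    fn = len(causal) - tp
    tn = L - len(causal) - fp
    return MetricsReport.from_counts(tp=tp, fp=fp, fn=fn, tn=tn)


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Average rates over replicate datasets (counts are summed)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out = MetricsReport(
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        tn=sum(r.tn for r in reports),
        recall=float(np.mean([r.recall for r in reports])),
        fdr=float(np.mean([r.fdr for r in reports])),
        fpr=float(np.mean([r.fpr for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        n_datasets=len(reports),
    )
    return out
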