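"""True skill statistic and the ABC distance 1 - TSS between predation matrices.

The TSS scores a predicted binary web against an observed one over all S**2
cells (diagonal included):

    TSS = (TP*TN - FP*FN) / ((TP + FN) * (FP + TN))

It is +1 for a perfect prediction, 0 for predictions no better than random
(e.g. an all-ones web), and -1 for a perfect anti-prediction. The ABC
distance is 1 - TSS, which ranges over [0, 2] and is 0 iff the prediction
matches the observation exactly.

The statistic is undefined when the observed web has no links (TP+FN = 0) or
no absences (FP+TN = 0); such degenerate observations raise
:class:`~adbm.exceptions.DegenerateWebError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateWebError, FormatError
from .webio import PredationMatrix

__all__ = ["ConfusionCounts", "confusion_counts", "true_skill_statistic", "distance"]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation of observed vs predicted link presence."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(observed: PredationMatrix, predicted: PredationMatrix) -> ConfusionCounts:
    """Count TP/TN/FP/FN cells between two webs on the same community."""
    if observed.community.node_ids != predicted.community.node_ids:
        raise FormatError("observed and predicted webs are on different communities")
    obs = observed.links.astype(bool)
    pred = predicted.links.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(obs & pred)),
        TN=int(np.sum(~obs & ~pred)),
        FP=int(np.sum(~obs & pred)),
        FN=int(np.sum(obs & ~pred)),
    )


def true_skill_statistic(c: ConfusionCounts) -> float:
    """TSS from confusion counts; exact integer numerator, one float division."""
    pos = c.TP + c.FN
    neg = c.FP + c.TN
    if pos == 0:
        raise DegenerateWebError("observed web has no links; TSS is undefined")
    if neg == 0:
        raise DegenerateWebError("observed web has no absences; TSS is undefined")
    return (c.TP * c.TN - c.FP * c.FN) / (pos * neg)


def distance(observed: PredationMatrix, predicted: PredationMatrix) -> float:
    """ABC distance 1 - TSS, in [0, 2]; 0 iff the webs are identical."""
    return 1.0 - true_skill_statistic(confusion_counts(observed, predicted))
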