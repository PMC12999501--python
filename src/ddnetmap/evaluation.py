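"""Evaluation helpers for synthetic-benchmark recovery."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError

__all__ = ["rank_auroc"]


def rank_auroc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    ``labels`` are binary (1 = positive); ties in ``scores`` receive
    mid-ranks, so the result equals the probability that a random
    positive outscores a random negative (ties counting half).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUROC needs both positive and negative labels")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
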