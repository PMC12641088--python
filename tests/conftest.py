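import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from aseries.data import ResponseTable
from aseries.response import reference_standard_response


@pytest.fixture(scope="session")
def standard():
    """The published ND standard response."""
    return reference_standard_response()


@pytest.fixture(scope="session")
def standard_scores(standard):
    """The 11 standard scores in ascending order."""
    return np.sort(standard.means.to_numpy(float))


def make_response_table(score_matrix, groups=None, ids=None) -> ResponseTable:
    """Build a ResponseTable from an (n_participants, 11) integer matrix."""
    score_matrix = np.asarray(score_matrix)
    n = score_matrix.shape[0]
    ids = ids or [f"S{i:02d}" for i in range(n)]
    groups = groups or ["ND"] * n
    rows = [
        (pid, sid, int(score))
        for pid, row in zip(ids, score_matrix)
        for sid, score in zip(range(1, 12), row)
    ]
    scores = pd.DataFrame(rows, columns=["participant_id", "sentence_id", "score"])
    meta = pd.DataFrame({"participant_id": ids, "group": groups})
    return ResponseTable(scores=scores, meta=meta)


def label_agreement(true_labels, pred_labels) -> float:
    """Fraction of points matched under the best one-to-one label mapping."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    tl, pl = np.unique(true_labels), np.unique(pred_labels)
    contingency = np.zeros((tl.size, pl.size))
    for i, t in enumerate(tl):
        for j, p in enumerate(pl):
            contingency[i, j] = np.sum((true_labels == t) & (pred_labels == p))
    rows, cols = linear_sum_assignment(-contingency)
    return contingency[rows, cols].sum() / true_labels.size
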