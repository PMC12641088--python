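"""Standard response and the pivotal-constrained regression features.

The standard response of each sentence is the mean score among the
non-demented (ND) participants; sorting sentences by it recovers the
past-to-future ordering of the adverbs.  Each participant's eleven
scores y are then regressed on the standard scores x with a line
constrained through the pivotal present point (5, 5),

    y = k (x - 5) + 5,

and the estimated slope k together with the determination coefficient
(fraction of response variance explained by the line) form the
two-dimensional feature used by the clustering stage.  The standard
response itself yields slope 1 and determination coefficient 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseTable
from .sentences import SENTENCES, ND_REFERENCE_MEANS, ND_REFERENCE_SDS, Sentence

PIVOT = 5.0  # the "present" anchor on both axes


class DegenerateDesignError(ValueError):
    """All abscissa values equal the pivot; the slope is unidentifiable."""


@dataclass
class StandardResponse:
    """Per-sentence ND mean/SD and the ascending sentence ordering.

    ``table`` is indexed by sentence_id with columns mean, sd, n and
    single_observation (SD reported as 0 by convention when n == 1).
    ``order`` lists sentence ids by ascending mean (ties by id).
    """

    table: pd.DataFrame
    order: list[int]

    @property
    def means(self) -> pd.Series:
        return self.table["mean"]

    def x_for(self, sentence_ids) -> np.ndarray:
        """Standard scores aligned to the given sentence ids."""
        return self.table["mean"].reindex(sentence_ids).to_numpy(float)


def reference_standard_response() -> StandardResponse:
    """The published ND standard response (means and SDs per sentence)."""
    ids = sorted(ND_REFERENCE_MEANS)
    table = pd.DataFrame(
        {
            "mean": [ND_REFERENCE_MEANS[i] for i in ids],
            "sd": [ND_REFERENCE_SDS[i] for i in ids],
            "n": np.nan,
            "single_observation": False,
        },
        index=pd.Index(ids, name="sentence_id"),
    )
    order = sorted(ids, key=lambda i: (ND_REFERENCE_MEANS[i], i))
    return StandardResponse(table=table, order=order)


def compute_standard_response(
    responses: ResponseTable, sentences: tuple[Sentence, ...] = SENTENCES
) -> StandardResponse:
    """Mean and sample SD of each sentence's score among ND participants.

    SD uses the n-1 denominator; a sentence scored by a single ND
    participant gets SD 0 with ``single_observation`` flagged.  A
    sentence with no ND observation raises ``ValueError``.
    """
    nd = responses.restrict_group("ND")
    ids = [s.id for s in sentences]
    rows = []
    for sid in ids:
        vals = nd.scores.loc[nd.scores["sentence_id"] == sid, "score"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"sentence {sid} has no ND observations")
        mean = float(vals.mean())
        single = vals.size == 1
        sd = 0.0 if single else float(vals.std(ddof=1))
        rows.append((sid, mean, sd, vals.size, single))
    table = pd.DataFrame(
        rows, columns=["sentence_id", "mean", "sd", "n", "single_observation"]
    ).set_index("sentence_id")
    order = sorted(ids, key=lambda i: (table.at[i, "mean"], i))
    return StandardResponse(table=table, order=order)


@dataclass(frozen=True)
class PivotalFit:
    """Slope and determination coefficient of one participant's fit.

    ``dc_raw`` may be negative (the constrained line can explain less
    variance than the mean); ``dc`` clamps it into [0, 1] for the
    clustering plane.  ``dc_defined`` is False when the participant's
    scores are constant (zero total variance), in which case both dc
    fields are NaN and the participant is excluded from clustering.
    """

    participant_id: str
    slope: float
    dc_raw: float
    dc: float
    n_points: int
    dc_defined: bool = True


def fit_pivotal(x, y, participant_id: str = "") -> PivotalFit:
    """Least-squares fit of y = k(x-5)+5 through the pivot (5, 5).

    The closed form is k = sum((x-5)(y-5)) / sum((x-5)^2); the
    determination coefficient is 1 - SS_res/SS_tot with SS_tot taken
    about the mean of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    dx = x - PIVOT
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DegenerateDesignError("all x equal the pivot 5; slope unidentifiable")
    slope = float(dx @ (y - PIVOT)) / sxx
    resid = y - (slope * dx + PIVOT)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return PivotalFit(participant_id, slope, np.nan, np.nan, x.size, False)
    dc_raw = 1.0 - ss_res / ss_tot
    dc = float(min(max(dc_raw, 0.0), 1.0))
    return PivotalFit(participant_id, slope, dc_raw, dc, x.size)


def extract_features(
    responses: ResponseTable,
    standard: StandardResponse,
    n_sentences: int = 11,
) -> pd.DataFrame:
    """Per-participant pivotal fits against the standard scores.

    Returns one row per participant with columns participant_id, group,
    slope, dc_raw, dc, n_points, excluded_reason.  Participants missing
    sentences are excluded (reason ``incomplete``); constant responders
    keep their slope but are excluded from clustering (reason
    ``constant_response``).
    """
    if responses.scores.empty:
        raise ValueError("empty response table")
    groups = responses.group_of()
    complete = set(responses.complete_participants(n_sentences))
    rows = []
    for pid in responses.participant_ids:
        group = groups[pid]
        if pid not in complete:
            rows.append((pid, group, np.nan, np.nan, np.nan, 0, "incomplete"))
            continue
        scores = responses.scores_of(pid)
        x = standard.x_for(scores.index)
        fit = fit_pivotal(x, scores.to_numpy(float), pid)
        reason = "" if fit.dc_defined else "constant_response"
        rows.append(
            (pid, group, fit.slope, fit.dc_raw, fit.dc, fit.n_points, reason)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "slope", "dc_raw", "dc",
            "n_points", "excluded_reason",
        ],
    )


def feature_points(features: pd.DataFrame) -> pd.DataFrame:
    """Rows of ``extract_features`` output eligible for clustering."""
    ok = features["excluded_reason"] == ""
    return features.loc[ok, ["participant_id", "group", "slope", "dc"]].reset_index(
        drop=True
    )
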