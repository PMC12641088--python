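"""Domain tables, validation and CSV I/O shared by all analysis stages.

Two tabular inputs drive the pipeline: long-format questionnaire
responses (one row per participant x sentence, score 1-9) and regional
cerebral-blood-flow values for the 24 arterial territories of the
stereotactic ROI template (12 territories x 2 hemispheres).  Loaders
validate exhaustively and report every offending row rather than
silently dropping data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("ND", "MCI", "AD")
CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

#: The 12 arterial territories of the stereotactic ROI template, in the
#: conventional display order.  Numbering regions as (territory, right
#: then left) makes the bilateral pericallosal territory regions 15/16.
TERRITORIES = (
    "callosomarginal",
    "precentral",
    "central",
    "parietal",
    "angular",
    "temporal",
    "posterior",
    "pericallosal",
    "lenticular",
    "thalamus",
    "hippocampus",
    "cerebellum",
)
HEMISPHERES = ("right", "left")

#: Canonical region identifiers, region id 1..24 = position + 1.
REGIONS: tuple[str, ...] = tuple(
    f"{territory}_{hemi}" for territory in TERRITORIES for hemi in HEMISPHERES
)

#: Mapping from canonical identifiers to display names as printed by the
#: ROI-template software.
_DISPLAY_TERRITORY = {
    "callosomarginal": "cal. marginal",
    "precentral": "precentral",
    "central": "central",
    "parietal": "parietal",
    "angular": "angular",
    "temporal": "temporal",
    "posterior": "posterior",
    "pericallosal": "pericallosal",
    "lenticular": "lenticular nucleus",
    "thalamus": "thalamus",
    "hippocampus": "hippocampus",
    "cerebellum": "cerebellum",
}
REGION_DISPLAY: dict[str, str] = {
    f"{t}_{h}": f"{'R' if h == 'right' else 'L'} {_DISPLAY_TERRITORY[t]}"
    for t in TERRITORIES
    for h in HEMISPHERES
}


def region_id(region: str) -> int:
    """1-based region number of a canonical region identifier."""
    return REGIONS.index(region) + 1


def territory_of(region: str) -> str:
    territory, _, hemi = region.rpartition("_")
    return territory


class ValidationError(ValueError):
    """Input failed validation; ``problems`` lists every offence found."""

    def __init__(self, message: str, problems: Sequence[str] = ()):
        self.problems = list(problems)
        detail = "".join(f"\n  - {p}" for p in self.problems)
        super().__init__(message + detail)


class SchemaError(ValidationError):
    """A required column could not be resolved."""


@dataclass(frozen=True)
class Participant:
    """Study participant metadata.

    ``group`` must be consistent with the CDR stage when both are given
    (CDR 0 -> ND, 0.5 -> MCI, >= 1 -> AD).
    """

    id: str
    group: str
    age: float | None = None
    sex: str | None = None
    cdr: float | None = None
    mmse: int | None = None
    response_time: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.cdr is not None:
            if self.cdr not in CDR_LEVELS:
                raise ValueError(f"cdr must be one of {CDR_LEVELS}, got {self.cdr}")
            expected = "ND" if self.cdr == 0 else "MCI" if self.cdr == 0.5 else "AD"
            if self.group != expected:
                raise ValueError(
                    f"participant {self.id}: group {self.group} inconsistent "
                    f"with CDR {self.cdr} (expected {expected})"
                )
        if self.mmse is not None and not 0 <= self.mmse <= 30:
            raise ValueError(f"mmse must be in 0..30, got {self.mmse}")
        if self.response_time is not None and self.response_time < 0:
            raise ValueError("response_time must be >= 0 seconds")


@dataclass
class ResponseTable:
    """Long-format questionnaire scores plus per-participant metadata.

    ``scores`` has columns participant_id, sentence_id, score; ``meta``
    one row per participant with at least participant_id and group.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = self.scores.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.meta["participant_id"])

    def group_of(self) -> pd.Series:
        return self.meta.set_index("participant_id")["group"]

    def scores_of(self, participant_id: str) -> pd.Series:
        """Scores of one participant indexed by sentence id."""
        sub = self.scores[self.scores["participant_id"] == participant_id]
        return sub.set_index("sentence_id")["score"].sort_index()

    def complete_participants(self, n_sentences: int = 11) -> list[str]:
        counts = self.scores.groupby("participant_id")["sentence_id"].nunique()
        return [p for p in self.participant_ids if counts.get(p, 0) == n_sentences]

    def incomplete_participants(self, n_sentences: int = 11) -> list[str]:
        complete = set(self.complete_participants(n_sentences))
        return [p for p in self.participant_ids if p not in complete]

    def restrict_group(self, group: str) -> "ResponseTable":
        meta = self.meta[self.meta["group"] == group]
        keep = set(meta["participant_id"])
        return ResponseTable(
            self.scores[self.scores["participant_id"].isin(keep)], meta
        )


@dataclass
class CBFTable:
    """Long-format regional CBF values (ml/100 g/min), 24 regions."""

    values: pd.DataFrame  # columns: participant_id, region, cbf

    def __post_init__(self) -> None:
        self.values = self.values.reset_index(drop=True)

    @property
    def participant_ids(self) -> list[str]:
        return list(dict.fromkeys(self.values["participant_id"]))

    def wide(self) -> pd.DataFrame:
        """Participant x region matrix with columns in canonical order."""
        wide = self.values.pivot(
            index="participant_id", columns="region", values="cbf"
        )
        present = [r for r in REGIONS if r in wide.columns]
        return wide[present]


# ---------------------------------------------------------------------------
# CSV round trip

_RESPONSE_SCHEMA = {
    "participant_id": "participant_id",
    "group": "group",
    "sentence_id": "sentence_id",
    "score": "score",
}
_META_OPTIONAL = ("age", "sex", "cdr", "mmse", "response_time_s")


def _resolve_columns(
    df: pd.DataFrame, schema: Mapping[str, str], required: Sequence[str]
) -> dict[str, str]:
    missing = [schema.get(k, k) for k in required if schema.get(k, k) not in df.columns]
    if missing:
        raise SchemaError(
            "missing required column(s)", [f"column {c!r} not found" for c in missing]
        )
    return {k: schema.get(k, k) for k in required}


def read_response_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> ResponseTable:
    """Read and validate a long-format response CSV.

    ``schema`` maps canonical column names (participant_id, group,
    sentence_id, score, plus optional age/sex/cdr/mmse/response_time_s)
    to the file's actual column names.
    """
    schema = dict(_RESPONSE_SCHEMA) | dict(schema or {})
    df = pd.read_csv(path)
    cols = _resolve_columns(df, schema, list(_RESPONSE_SCHEMA))
    problems: list[str] = []
    rows = df.rename(columns={v: k for k, v in cols.items()})

    for idx, row in rows.iterrows():
        line = idx + 2  # header is line 1
        score = row["score"]
        if not (float(score).is_integer() and 1 <= int(score) <= 9):
            problems.append(f"row {line}: score {score!r} not an integer in 1..9")
        sid = row["sentence_id"]
        if not (float(sid).is_integer() and 1 <= int(sid) <= 11):
            problems.append(f"row {line}: sentence_id {sid!r} not in 1..11")
        if row["group"] not in GROUPS:
            problems.append(f"row {line}: group {row['group']!r} not in {GROUPS}")
    dup = rows.duplicated(subset=["participant_id", "sentence_id"], keep=False)
    for idx in rows.index[dup]:
        problems.append(
            f"row {idx + 2}: duplicate (participant, sentence) pair "
            f"({rows.at[idx, 'participant_id']}, {rows.at[idx, 'sentence_id']})"
        )
    if problems:
        raise ValidationError(f"invalid response table {path}", problems)

    scores = rows[["participant_id", "sentence_id", "score"]].astype(
        {"sentence_id": int, "score": int}
    )
    meta_cols = ["participant_id", "group"] + [
        schema.get(c, c) for c in _META_OPTIONAL if schema.get(c, c) in df.columns
    ]
    rename = {schema.get(c, c): c for c in _META_OPTIONAL}
    meta = (
        rows[[c for c in meta_cols if c in rows.columns]]
        .rename(columns=rename)
        .drop_duplicates(subset="participant_id")
        .reset_index(drop=True)
    )
    return ResponseTable(scores=scores, meta=meta)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    """Write a response table to CSV, merging metadata into each row."""
    merged = table.scores.merge(table.meta, on="participant_id", how="left")
    lead = ["participant_id", "group", "sentence_id", "score"]
    rest = [c for c in merged.columns if c not in lead]
    merged[lead + rest].to_csv(path, index=False)


def read_cbf_table(path: str | Path) -> CBFTable:
    """Read and validate a long-format CBF CSV.

    Expected columns: participant_id, region, cbf_ml_100g_min (or cbf).
    """
    df = pd.read_csv(path)
    if "cbf" not in df.columns and "cbf_ml_100g_min" in df.columns:
        df = df.rename(columns={"cbf_ml_100g_min": "cbf"})
    missing = [c for c in ("participant_id", "region", "cbf") if c not in df.columns]
    if missing:
        raise SchemaError(
            "missing required column(s)", [f"column {c!r} not found" for c in missing]
        )
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        if row["region"] not in REGIONS:
            problems.append(
                f"row {line}: unknown region {row['region']!r}; legal names: "
                + ", ".join(REGIONS)
            )
        if not np.isfinite(row["cbf"]) or row["cbf"] <= 0:
            problems.append(f"row {line}: CBF {row['cbf']!r} not strictly positive")
    dup = df.duplicated(subset=["participant_id", "region"], keep=False)
    for idx in df.index[dup]:
        problems.append(
            f"row {idx + 2}: duplicate (participant, region) pair "
            f"({df.at[idx, 'participant_id']}, {df.at[idx, 'region']})"
        )
    if problems:
        raise ValidationError(f"invalid CBF table {path}", problems)
    return CBFTable(df[["participant_id", "region", "cbf"]].copy())


def write_cbf_table(table: CBFTable, path: str | Path) -> None:
    out = table.values.rename(columns={"cbf": "cbf_ml_100g_min"})
    out.to_csv(path, index=False)
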