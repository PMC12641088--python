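"""Group comparisons: one-way ANOVA, Tukey HSD, Bonferroni region screen.

Demographic variables are compared across diagnostic groups or response
clusters by classical equal-variance one-way ANOVA followed by Tukey's
honestly-significant-difference test (Tukey-Kramer for unequal group
sizes).  The regional CBF screen runs one ANOVA per arterial territory
and applies a Bonferroni-corrected threshold alpha/m over the m = 24
territories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import REGIONS, CBFTable


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    group_sds: dict
    group_ns: dict


def _as_groups(values_by_group) -> dict:
    if isinstance(values_by_group, Mapping):
        return {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(values_by_group)}


def anova_oneway(values_by_group) -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    g = len(groups)
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = g - 1, n_total - g
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_sds={k: float(v.std(ddof=1)) for k, v in groups.items()},
        group_ns={k: int(v.size) for k, v in groups.items()},
    )


def tukey_hsd(values_by_group, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Tukey-Kramer comparisons (studentized range).

    Returns a frame with columns group1, group2, diff, p_adj, ci_low,
    ci_high at the given family confidence level.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    keys = list(groups)
    res = sps.tukey_hsd(*[groups[k] for k in keys])
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            rows.append(
                (
                    keys[i],
                    keys[j],
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                    float(ci.low[i, j]),
                    float(ci.high[i, j]),
                )
            )
    return pd.DataFrame(
        rows, columns=["group1", "group2", "diff", "p_adj", "ci_low", "ci_high"]
    )


@dataclass
class RegionScreenResult:
    """Per-region ANOVA across clusters with Bonferroni correction."""

    frame: pd.DataFrame          # region, f, df_between, df_within, p, significant
    bonferroni_alpha: float
    anovas: dict[str, AnovaResult]

    @property
    def significant_regions(self) -> list[str]:
        return list(self.frame.loc[self.frame["significant"], "region"])


def screen_regions(
    cbf: CBFTable,
    labels: Mapping[str, int],
    alpha: float = 0.05,
    m: int = 24,
    strict: bool = True,
) -> RegionScreenResult:
    """ANOVA of CBF across clusters in each region, threshold alpha/m.

    ``labels`` maps participant id to cluster.  In strict mode a region
    missing for some labelled participant is an error; otherwise such
    regions are dropped with a note in the result frame.
    """
    labels = dict(labels)
    if len(set(labels.values())) < 2:
        raise ValueError("need at least two clusters")
    unlabelled = [p for p in cbf.participant_ids if p not in labels]
    if unlabelled:
        raise ValueError(f"participants without cluster label: {unlabelled}")
    wide = cbf.wide()
    threshold = alpha / m
    rows, anovas = [], {}
    for region in (r for r in REGIONS if r in wide.columns):
        col = wide[region]
        if col.isna().any():
            if strict:
                raise ValueError(f"region {region} missing for some participants")
            continue
        by_cluster: dict[int, list[float]] = {}
        for pid, value in col.items():
            by_cluster.setdefault(labels[pid], []).append(value)
        res = anova_oneway(by_cluster)
        anovas[region] = res
        rows.append(
            (region, res.f, res.df_between, res.df_within, res.p,
             res.p < threshold)
        )
    frame = pd.DataFrame(
        rows, columns=["region", "f", "df_between", "df_within", "p", "significant"]
    )
    return RegionScreenResult(frame=frame, bonferroni_alpha=threshold, anovas=anovas)


def group_summary(
    data: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean +/- SD per group with ANOVA F/p and pairwise Tukey p-values.

    Mirrors the usual background-characteristics table layout: one row
    per variable.
    """
    rows = []
    for var in variables:
        sub = data[[group_col, var]].dropna()
        groups = {
            k: v[var].to_numpy(float) for k, v in sub.groupby(group_col)
        }
        res = anova_oneway(groups)
        tuk = tukey_hsd(groups, alpha=alpha)
        pairs = {
            f"{a} vs {b}": p
            for a, b, p in zip(tuk["group1"], tuk["group2"], tuk["p_adj"])
        }
        row = {"variable": var, "f": res.f, "df": (res.df_between, res.df_within),
               "p": res.p}
        for k in groups:
            row[f"{k} mean"] = res.group_means[k]
            row[f"{k} sd"] = res.group_sds[k]
            row[f"{k} n"] = res.group_ns[k]
        row.update(pairs)
        rows.append(row)
    return pd.DataFrame(rows)
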