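"""Synthetic cohorts with the response and CBF structure the pipeline assumes.

Three response regimes emulate the empirically observed clusters:

* ``linear`` -- intact temporal orientation: responses follow the
  standard scores with slope near 1 and small noise;
* ``coarse`` -- three-grade scoring: items are collapsed to far past
  (1), present (5) or far future (9) by the adverb's nominal category,
  which steepens the fitted slope beyond 1.5;
* ``flat`` -- degraded orientation: responses hover near the present
  pivot with weak dependence on the item and large noise, giving slopes
  below 1 and low explained variance.

Regional CBF is drawn per participant around territory baselines with
cluster-dependent decrements, largest in the bilateral pericallosal
territory, so blood flow declines over clusters 1 -> 2 -> 3 with the
strongest separation where the empirical study found it.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import REGIONS, CBFTable, ResponseTable, territory_of
from .patlak import TimeActivityCurve, _cumulative_input
from .response import StandardResponse, reference_standard_response
from .sentences import SENTENCES, nominal_category

REGIMES = ("linear", "coarse", "flat")
_COARSE_SCORE = {"past": 1.0, "present": 5.0, "future": 9.0}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes and per-regime response parameters.

    Noise scales are calibrated against the spread of the published
    standard response (per-sentence SDs 0.41-0.75 on the nine-point
    scale).
    """

    n_linear: int = 20
    n_coarse: int = 15
    n_flat: int = 20
    linear_slope_mean: float = 1.0
    linear_slope_sd: float = 0.10
    linear_noise_sd: float = 0.4
    coarse_flip_prob: float = 0.05
    coarse_noise_sd: float = 0.5
    flat_slope: float = 0.35
    flat_noise_sd: float = 1.1

    def __post_init__(self) -> None:
        if min(self.n_linear, self.n_coarse, self.n_flat) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.coarse_flip_prob <= 1.0:
            raise ValueError("coarse_flip_prob must be a probability")
        for name in ("linear_slope_sd", "linear_noise_sd", "coarse_noise_sd",
                     "flat_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Territory baseline CBF means (ml/100 g/min), both hemispheres.
DEFAULT_BASELINES: dict[str, float] = {
    "callosomarginal": 44.0,
    "precentral": 45.0,
    "central": 46.0,
    "parietal": 45.0,
    "angular": 46.0,
    "temporal": 44.0,
    "posterior": 48.0,
    "pericallosal": 50.0,
    "lenticular": 52.0,
    "thalamus": 52.0,
    "hippocampus": 38.0,
    "cerebellum": 54.0,
}


@dataclass(frozen=True)
class CBFSpec:
    """Cluster-dependent regional CBF distribution.

    ``cluster_decrement`` lowers every territory mean per cluster;
    ``pericallosal_extra`` adds a further cluster-dependent drop in the
    bilateral pericallosal territory, making it the most separable
    region.
    """

    baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    sd: float = 4.5
    cluster_decrement: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 3.0, 3: 6.0}
    )
    pericallosal_extra: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 4.0, 3: 8.0}
    )

    def mean_for(self, region: str, cluster: int) -> float:
        territory = territory_of(region)
        mean = self.baselines[territory] - self.cluster_decrement[cluster]
        if territory == "pericallosal":
            mean -= self.pericallosal_extra[cluster]
        return mean

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        for cluster in self.cluster_decrement:
            for territory in self.baselines:
                if self.mean_for(f"{territory}_right", cluster) <= 0:
                    raise ValueError(
                        f"post-decrement mean for {territory}, cluster {cluster} "
                        "not positive"
                    )


def _discretize(y: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clip to the 1..9 scale."""
    rounded = np.sign(y) * np.floor(np.abs(y) + 0.5)
    return np.clip(rounded, 1, 9).astype(int)


# Demographic distributions conditional on regime (MMSE, response time),
# mirroring the observed decline over clusters 1 -> 2 -> 3.
_GROUP_PROBS = {"linear": (0.45, 0.25, 0.30),
                "coarse": (0.0, 0.2, 0.8),
                "flat": (0.0, 0.1, 0.9)}
_MMSE = {"linear": (27.0, 2.0), "coarse": (22.0, 2.5), "flat": (20.0, 3.0)}
_RESPONSE_TIME = {"linear": (150.0, 60.0), "coarse": (277.0, 120.0),
                  "flat": (400.0, 150.0)}


def gen_responses(
    spec: CohortSpec,
    standard: StandardResponse | None = None,
    seed: int = 0,
) -> tuple[ResponseTable, pd.DataFrame]:
    """Generate a cohort's response table and the true regime labels.

    Returns (table, truth) where truth has columns participant_id,
    regime, regime_index (1..3 in the order linear, coarse, flat).
    """
    if standard is None:
        standard = reference_standard_response()
    rng = np.random.default_rng(seed)
    sentence_ids = [s.id for s in SENTENCES]
    x = standard.x_for(sentence_ids)
    coarse_target = np.array(
        [_COARSE_SCORE[nominal_category(s)] for s in SENTENCES]
    )
    score_rows, meta_rows, truth_rows = [], [], []
    counts = {"linear": spec.n_linear, "coarse": spec.n_coarse, "flat": spec.n_flat}
    pid_no = 0
    for regime_index, regime in enumerate(REGIMES, start=1):
        for _ in range(counts[regime]):
            pid_no += 1
            pid = f"P{pid_no:03d}"
            if regime == "linear":
                slope = rng.normal(spec.linear_slope_mean, spec.linear_slope_sd)
                y = slope * (x - 5.0) + 5.0 + rng.normal(0, spec.linear_noise_sd, x.size)
            elif regime == "coarse":
                y = coarse_target.copy()
                flips = rng.random(x.size) < spec.coarse_flip_prob
                for i in np.flatnonzero(flips):
                    # misgrade into an adjacent category (past<->present<->future)
                    if y[i] == 5.0:
                        y[i] = rng.choice((1.0, 9.0))
                    else:
                        y[i] = 5.0
                y = y + rng.normal(0, spec.coarse_noise_sd, x.size)
            else:
                y = (5.0 + spec.flat_slope * (x - 5.0)
                     + rng.normal(0, spec.flat_noise_sd, x.size))
            scores = _discretize(y)
            score_rows += [(pid, sid, int(s)) for sid, s in zip(sentence_ids, scores)]

            group = rng.choice(("ND", "MCI", "AD"), p=_GROUP_PROBS[regime])
            cdr = {"ND": 0.0, "MCI": 0.5}.get(group)
            if cdr is None:
                cdr = float(rng.choice((1.0, 2.0, 3.0), p=(0.3, 0.5, 0.2)))
            mmse_mu, mmse_sd = _MMSE[regime]
            rt_mu, rt_sd = _RESPONSE_TIME[regime]
            meta_rows.append(
                (
                    pid,
                    group,
                    float(np.clip(rng.normal(80.0, 4.5), 60, 95)),
                    str(rng.choice(("M", "F"))),
                    cdr,
                    int(np.clip(round(rng.normal(mmse_mu, mmse_sd)), 0, 30)),
                    float(max(rng.normal(rt_mu, rt_sd), 10.0)),
                )
            )
            truth_rows.append((pid, regime, regime_index))
    scores = pd.DataFrame(
        score_rows, columns=["participant_id", "sentence_id", "score"]
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=["participant_id", "group", "age", "sex", "cdr", "mmse",
                 "response_time_s"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "regime", "regime_index"]
    )
    return ResponseTable(scores=scores, meta=meta), truth


def gen_cbf(
    labels: Mapping[str, int], spec: CBFSpec | None = None, seed: int = 0
) -> CBFTable:
    """Regional CBF per labelled participant, cluster-dependent means."""
    spec = spec or CBFSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for pid, cluster in labels.items():
        for region in REGIONS:
            value = rng.normal(spec.mean_for(region, cluster), spec.sd)
            rows.append((pid, region, max(float(value), 0.1)))
    return CBFTable(pd.DataFrame(rows, columns=["participant_id", "region", "cbf"]))


def gen_tac(
    k1: float,
    v0: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    n_frames: int = 120,
    frame_s: float = 1.0,
) -> TimeActivityCurve:
    """Dynamic time-activity curve from the two-compartment linear model.

    The plasma input is a gamma-variate bolus; the tissue curve is
    CT = (K1/60) * integral(CP) + V0 * CP computed with the same
    from-zero trapezoidal rule the Patlak transform uses, so the
    noiseless curve is exactly linear in Patlak coordinates.  Gaussian
    noise with SD ``noise_frac`` * max(CT) is added to CT.  ``k1`` is in
    1/min; frame times are midpoints of ``n_frames`` frames of
    ``frame_s`` seconds.
    """
    if k1 < 0 or v0 < 0:
        raise ValueError("k1 and v0 must be >= 0")
    rng = np.random.default_rng(seed)
    times = (np.arange(n_frames) + 0.5) * frame_s
    tau = 30.0  # seconds to bolus peak
    cp = 100.0 * (times / tau) ** 3 * np.exp(3.0 * (1.0 - times / tau))
    ct = (k1 / 60.0) * _cumulative_input(times, cp) + v0 * cp
    if noise_frac > 0:
        ct = ct + rng.normal(0.0, noise_frac * ct.max(), ct.size)
    return TimeActivityCurve(times=times, cp=cp, ct=ct)
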