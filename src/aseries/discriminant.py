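"""Leave-one-out LDA and the exhaustive single/pair region search.

A Gaussian linear discriminant with pooled within-class covariance and
empirical class priors predicts cluster membership from regional CBF.
Generalisation is measured by leave-one-out cross-validation: each
participant is predicted by a discriminant refitted on all others.  The
search evaluates every single region (24 models) and, optionally, every
unordered pair (276 models), ranking by LOO hit rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .data import REGIONS, CBFTable

log = logging.getLogger(__name__)

RIDGE_SCALE = 1e-8  # relative ridge applied if the pooled covariance is singular


@dataclass(frozen=True)
class DiscriminantResult:
    """LOO performance of one feature set."""

    feature_set: tuple[str, ...]
    hit_rate: float
    confusion: np.ndarray        # rows = true class, columns = predicted
    classes: tuple
    per_class_hit: tuple[float, ...]

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance singular even after ridge regularisation."""


def _pooled_lda(train_X: np.ndarray, train_y: np.ndarray):
    """Fit pooled-covariance LDA; returns (classes, coefs, intercepts)."""
    classes, counts = np.unique(train_y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes in the training labels")
    n, p = train_X.shape
    means = np.stack([train_X[train_y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = train_X[train_y == c] - mu
        pooled += d.T @ d
    pooled /= max(n - classes.size, 1)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        ridge = RIDGE_SCALE * np.trace(pooled) / classes.size
        if ridge <= 0:
            raise SingularCovarianceError(
                "pooled covariance is singular and has zero trace"
            )
        log.info("pooled covariance singular; applying ridge %.3g", ridge)
        try:
            inv = np.linalg.inv(pooled + ridge * np.eye(p))
        except np.linalg.LinAlgError as err:
            raise SingularCovarianceError(
                "pooled covariance singular after ridge"
            ) from err
    priors = counts / n
    coefs = means @ inv                                  # (g, p)
    intercepts = -0.5 * np.einsum("gp,gp->g", coefs, means) + np.log(priors)
    return classes, coefs, intercepts


def lda_fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    uniform_priors: bool = False,
) -> np.ndarray:
    """Predict test labels with pooled-covariance Gaussian LDA.

    The discriminant score of class g at x is
    x' S^-1 mu_g - mu_g' S^-1 mu_g / 2 + log pi_g with S the pooled
    within-class covariance; prediction is the argmax, ties resolved
    toward the smaller class label.  ``uniform_priors`` replaces the
    empirical class frequencies pi_g by 1/g.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y)
    classes, coefs, intercepts = _pooled_lda(train_X, train_y)
    if uniform_priors:
        counts = np.array([(train_y == c).sum() for c in classes])
        intercepts = intercepts - np.log(counts / train_y.size) + np.log(1 / classes.size)
    scores = test_X @ coefs.T + intercepts
    return classes[np.argmax(scores, axis=1)]


def loo_hit_rate(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[str] = (),
    uniform_priors: bool = False,
) -> DiscriminantResult:
    """Leave-one-out evaluation: refit on all-but-one, predict the one.

    If leaving a sample out removes its class from the training set,
    the prediction is necessarily made among the remaining classes;
    such folds are logged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).shape[0]:
        X = X.T
    y = np.asarray(y)
    n = y.size
    classes = np.unique(y)
    if n < classes.size + 2:
        raise ValueError("too few samples for leave-one-out")
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_y = y[mask]
        if index[y[i]] not in [index[c] for c in np.unique(train_y)]:
            log.info("fold %d: class %r absent from training set", i, y[i])
        pred = lda_fit_predict(
            X[mask], train_y, X[i : i + 1], uniform_priors=uniform_priors
        )[0]
        confusion[index[y[i]], index[pred]] += 1
        mask[i] = True
    hits = np.diag(confusion)
    row_sums = confusion.sum(axis=1)
    return DiscriminantResult(
        feature_set=tuple(feature_set),
        hit_rate=float(hits.sum() / n),
        confusion=confusion,
        classes=tuple(classes.tolist()),
        per_class_hit=tuple((hits / np.maximum(row_sums, 1)).tolist()),
    )


def exhaustive_search(
    cbf: CBFTable,
    labels: Mapping[str, int],
    max_size: int = 2,
    uniform_priors: bool = False,
) -> list[DiscriminantResult]:
    """Evaluate every single region and (max_size 2) every region pair.

    Results are ranked by LOO hit rate, ties broken by region-id order,
    so "the best model" is reproducible.  For the full 24-region table
    this enumerates 24 single models plus 276 = 24*23/2 pairs.
    """
    if max_size not in (1, 2):
        raise ValueError("max_size must be 1 or 2")
    wide = cbf.wide()
    missing = [p for p in wide.index if p not in labels]
    if missing:
        raise ValueError(f"participants without cluster label: {missing}")
    if wide.isna().any().any():
        raise ValueError("CBF table incomplete for labelled participants")
    y = np.array([labels[p] for p in wide.index])
    regions = [r for r in REGIONS if r in wide.columns]
    feature_sets: list[tuple[str, ...]] = [(r,) for r in regions]
    if max_size == 2:
        feature_sets += list(combinations(regions, 2))
    results = [
        loo_hit_rate(wide[list(fs)].to_numpy(float), y, feature_set=fs,
                     uniform_priors=uniform_priors)
        for fs in feature_sets
    ]
    order = {r: i for i, r in enumerate(REGIONS)}
    results.sort(key=lambda r: (-r.hit_rate, tuple(order[f] for f in r.feature_set)))
    return results


def best_pair_exceeds_best_single(results: list[DiscriminantResult]) -> bool:
    """Whether any pair model beats the best single-region model."""
    singles = [r.hit_rate for r in results if len(r.feature_set) == 1]
    pairs = [r.hit_rate for r in results if len(r.feature_set) == 2]
    if not singles or not pairs:
        return False
    return max(pairs) > max(singles)
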