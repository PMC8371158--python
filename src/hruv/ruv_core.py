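"""Replicate-anchored removal of unwanted variation (RUV-III style).

The model for a mean-centred measurements x metabolites matrix Z is

    Z = X beta + W alpha + eps

where X holds the (unobserved) factors of interest, W the scores of k
unwanted factors and alpha their metabolite loadings.  Technical replicates
of the same biological sample should be identical, so the variation left
after projecting out replicate-group means is unwanted by construction:
alpha is estimated from the top-k right singular directions of the
replicate-residualised matrix, W by regressing the negative-control columns
of Z on the corresponding columns of alpha, and W alpha is subtracted.
Per-metabolite means are removed before and restored after adjustment so
the factor estimation is not polluted by baseline abundance differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hruv")

__all__ = [
    "ReplicateMap",
    "RuvError",
    "build_replicate_matrix",
    "mean_center",
    "restore_mean",
    "ruv3_adjust",
    "adjust_group",
    "select_negative_controls",
]


class RuvError(ValueError):
    pass


@dataclass
class ReplicateMap:
    """Indicator matrix mapping measurements to distinct biological samples.

    ``indicator`` has one row per measurement and one column per distinct
    sample; every row sums to 1.  Columns with sum >= 2 are replicate
    groups, and the replicate residual space — the orthogonal complement of
    the group-mean space — has rank S - G for S measurements and G columns.
    """

    indicator: np.ndarray
    group_ids: list[str]

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator, dtype=float)
        if ind.ndim != 2 or ind.shape[1] != len(self.group_ids):
            raise RuvError("indicator shape does not match group_ids")
        if not np.all((ind == 0) | (ind == 1)) or not np.all(ind.sum(axis=1) == 1):
            raise RuvError("indicator rows must be one-hot")
        self.indicator = ind

    @property
    def n_measurements(self) -> int:
        return self.indicator.shape[0]

    @property
    def n_groups(self) -> int:
        return self.indicator.shape[1]

    @property
    def residual_rank(self) -> int:
        return self.n_measurements - self.n_groups

    def replicated_groups(self) -> list[str]:
        sums = self.indicator.sum(axis=0)
        return [g for g, s in zip(self.group_ids, sums) if s >= 2]


def build_replicate_matrix(groups) -> ReplicateMap:
    """Build a :class:`ReplicateMap` from per-measurement group labels.

    Accepts any sequence of labels (or a pandas Series); measurement order
    is preserved and columns appear in first-occurrence order.
    """
    labels = list(pd.Series(groups))
    if len(labels) == 0:
        raise RuvError("cannot build a replicate matrix from an empty annotation")
    if any(lbl is None or (isinstance(lbl, float) and np.isnan(lbl)) for lbl in labels):
        raise RuvError("missing replicate_group label")
    group_ids: list[str] = []
    index: dict[str, int] = {}
    for lbl in labels:
        lbl = str(lbl)
        if lbl not in index:
            index[lbl] = len(group_ids)
            group_ids.append(lbl)
    ind = np.zeros((len(labels), len(group_ids)))
    for i, lbl in enumerate(labels):
        ind[i, index[str(lbl)]] = 1.0
    return ReplicateMap(ind, group_ids)


def mean_center(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove each metabolite's mean over all S measurements.

    ``Y`` is measurements x metabolites; returns the centred matrix and the
    per-metabolite means.
    """
    Y = np.asarray(Y, dtype=float)
    means = Y.mean(axis=0)
    return Y - means, means


def restore_mean(Z: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Add the per-metabolite means back; exact inverse of :func:`mean_center`."""
    return np.asarray(Z, dtype=float) + np.asarray(means, dtype=float)


def _resolve_controls(controls, n_metabolites: int) -> np.ndarray:
    if controls is None:
        return np.arange(n_metabolites)
    controls = np.asarray(controls)
    if controls.dtype == bool:
        if controls.size != n_metabolites:
            raise RuvError("boolean control mask has wrong length")
        controls = np.flatnonzero(controls)
    if controls.size == 0:
        raise RuvError("controls must be non-empty")
    if controls.min() < 0 or controls.max() >= n_metabolites:
        raise RuvError("control index out of range")
    return controls.astype(int)


def ruv3_adjust(
    Z: np.ndarray,
    rep_map: ReplicateMap,
    controls=None,
    k: int = 5,
    k_policy: str = "cap",
) -> np.ndarray:
    """Estimate and subtract k unwanted factors from a mean-centred matrix.

    Parameters
    ----------
    Z:
        Mean-centred S x M matrix (measurements x metabolites).
    rep_map:
        Replicate structure; at least one multi-member group is needed for
        any k > 0.
    controls:
        Negative-control metabolite indices or boolean mask; default all.
    k:
        Number of unwanted factors.  ``k=0`` returns ``Z`` unchanged.
    k_policy:
        ``"cap"`` silently lowers k to the replicate residual rank with a
        warning; ``"error"`` raises instead.
    """
    Z = np.asarray(Z, dtype=float)
    if np.isnan(Z).any():
        raise RuvError("ruv3_adjust requires a complete matrix; impute first")
    if Z.shape[0] != rep_map.n_measurements:
        raise RuvError("replicate map does not match the number of measurements")
    if k < 0:
        raise RuvError("k must be >= 0")
    if k == 0:
        return Z.copy()
    rank = rep_map.residual_rank
    if k > rank:
        if rank == 0:
            raise RuvError(
                "no replicate information: every group is a singleton "
                "(replicate residual rank 0)"
            )
        if k_policy == "error":
            raise RuvError(f"k={k} exceeds replicate residual rank {rank}")
        warnings.warn(
            f"k={k} exceeds replicate residual rank {rank}; capping",
            stacklevel=2,
        )
        logger.warning("ruv3_adjust: k capped from %d to %d", k, rank)
        k = rank
    ctrl = _resolve_controls(controls, Z.shape[1])

    # residualise replicate-group means: R_M Z = Z - M (M^T M)^-1 M^T Z
    ind = rep_map.indicator
    group_sizes = ind.sum(axis=0)
    group_means = (ind.T @ Z) / group_sizes[:, None]
    RZ = Z - ind @ group_means

    # loadings: top-k right singular directions of the residualised matrix;
    # directions with (numerically) zero singular value carry no replicate
    # evidence of unwanted variation and are never removed
    _, sv, vt = np.linalg.svd(RZ, full_matrices=False)
    rank_tol = max(RZ.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    n_informative = int(np.sum(sv > rank_tol))
    if n_informative == 0:
        return Z.copy()
    k = min(k, n_informative)
    alpha = vt[:k]  # k x M

    # scores: least-squares regression of the control columns of Z on the
    # control columns of alpha
    alpha_c = alpha[:, ctrl]  # k x C
    if np.linalg.matrix_rank(alpha_c) < k:
        raise RuvError(
            "singular control regression: control loadings do not span the "
            f"{k} unwanted directions; use more controls or a smaller k"
        )
    W, *_ = np.linalg.lstsq(alpha_c.T, Z[:, ctrl].T, rcond=None)
    W = W.T  # S x k
    return Z - W @ alpha


def adjust_group(
    Y: np.ndarray,
    rep_map: ReplicateMap,
    controls=None,
    k: int = 5,
    k_policy: str = "cap",
) -> np.ndarray:
    """Full replicate-anchored adjustment of a measurements x metabolites
    matrix: mean-centre, remove k unwanted factors, restore the means."""
    Z, means = mean_center(Y)
    Zhat = ruv3_adjust(Z, rep_map, controls=controls, k=k, k_policy=k_policy)
    return restore_mean(Zhat, means)


def select_negative_controls(
    batches,
    phenotype,
    n_controls: int,
) -> list[str]:
    """Rank metabolites by phenotype association and return the least
    associated ones as negative controls.

    Parameters
    ----------
    batches:
        List of :class:`~hruv.preprocess.AssayBatch`.
    phenotype:
        Mapping (or Series) from biological sample id / replicate group to a
        binary label; only individual samples are scored.
    n_controls:
        Number of controls to return.

    Per batch, each metabolite gets an ordinary two-sample t statistic
    between the phenotype classes; absolute statistics are ranked within
    each batch and ranks averaged across batches.  Batches where one class
    is absent are skipped with a warning.
    """
    phenotype = pd.Series(phenotype)
    mets = batches[0].values.index
    if n_controls > len(mets):
        raise RuvError(
            f"n_controls={n_controls} exceeds the {len(mets)} metabolites"
        )
    rank_sum = pd.Series(0.0, index=mets)
    n_used = 0
    for batch in batches:
        ann = batch.annotation
        mask = ann["sample_type"] == "individual"
        ids = ann.index[mask]
        labels = ann.loc[ids, "replicate_group"].map(phenotype)
        ok = labels.notna()
        ids, labels = ids[ok], labels[ok]
        classes = labels.unique()
        if len(classes) < 2:
            warnings.warn(
                f"select_negative_controls: batch {ann['batch'].iloc[0]} has "
                "a single phenotype class; skipped",
                stacklevel=2,
            )
            continue
        g0 = batch.values[ids[labels == classes[0]]]
        g1 = batch.values[ids[labels == classes[1]]]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, _ = stats.ttest_ind(g0, g1, axis=1, nan_policy="omit")
        score = pd.Series(np.abs(np.nan_to_num(t)), index=mets)
        rank_sum += score.rank(method="average")
        n_used += 1
    if n_used == 0:
        raise RuvError("no batch had both phenotype classes")
    order = rank_sum.sort_values(kind="stable").index
    return list(order[:n_controls])
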