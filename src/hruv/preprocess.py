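"""Pre-processing of per-batch signal matrices.

Raw peak areas are log2 transformed, metabolites detected in fewer than half
of all measurements are dropped, remaining missing entries are imputed with a
k-nearest-neighbour scheme, and outlying conditioning-QC injections are
screened out.  The original missing mask is carried through the whole
pipeline so imputed entries can be restored to missing afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger("hruv")

__all__ = [
    "AssayBatch",
    "PreprocessError",
    "log2_transform",
    "presence_filter",
    "knn_impute",
    "restore_missing",
    "qc_outlier_screen",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: annotation columns every AssayBatch needs
ANNOTATION_COLUMNS = ["batch", "run_index", "sample_id", "sample_type", "replicate_group"]

#: sample types counted as biological samples (smoother scope "all_samples")
BIOLOGICAL_TYPES = ("individual", "shortReplicate", "batchReplicate")


class PreprocessError(ValueError):
    pass


@dataclass
class AssayBatch:
    """A metabolite x measurement signal matrix with its sample annotation.

    ``values`` is indexed by metabolite id with one column per measurement;
    missing entries are ``NaN``.  ``annotation`` is indexed by measurement id
    (same order as the columns) and carries at least batch, run_index,
    sample_id, sample_type and replicate_group.  ``missing_mask`` records
    which entries were missing on input, surviving imputation so they can be
    restored later.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    scale: str = "raw"  # raw | log2 | ratio
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.annotation.index):
            raise PreprocessError(
                "AssayBatch: values columns and annotation index disagree"
            )
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
        if missing:
            raise PreprocessError(f"AssayBatch annotation lacks columns {missing}")
        for b, sub in self.annotation.groupby("batch"):
            runs = sub["run_index"].to_numpy()
            if len(runs) > 1 and not np.all(np.diff(runs) > 0):
                raise PreprocessError(
                    f"AssayBatch: run indices within batch {b} must be "
                    "strictly increasing"
                )
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        elif (
            not self.missing_mask.index.equals(self.values.index)
            or not self.missing_mask.columns.equals(self.values.columns)
        ):
            raise PreprocessError("missing_mask shape does not match values")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_measurements(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **kwargs) -> "AssayBatch":
        out = replace(
            self,
            values=kwargs.get("values", self.values).copy(),
            annotation=kwargs.get("annotation", self.annotation).copy(),
            scale=kwargs.get("scale", self.scale),
            missing_mask=kwargs.get("missing_mask", self.missing_mask).copy(),
        )
        return out

    def subset_measurements(self, keep: pd.Index | list) -> "AssayBatch":
        keep = pd.Index(keep)
        return AssayBatch(
            values=self.values.loc[:, keep].copy(),
            annotation=self.annotation.loc[keep].copy(),
            scale=self.scale,
            missing_mask=self.missing_mask.loc[:, keep].copy(),
        )

    def subset_metabolites(self, keep) -> "AssayBatch":
        keep = pd.Index(keep)
        return AssayBatch(
            values=self.values.loc[keep].copy(),
            annotation=self.annotation.copy(),
            scale=self.scale,
            missing_mask=self.missing_mask.loc[keep].copy(),
        )


def log2_transform(batch: AssayBatch) -> AssayBatch:
    """Base-2 log of every observed signal; requires strictly positive values.

    Non-positive observed entries raise, naming the metabolite and
    measurement — values are never silently clamped.
    """
    if batch.scale != "raw":
        raise PreprocessError(f"log2_transform expects raw scale, got {batch.scale!r}")
    vals = batch.values
    bad = (vals <= 0) & ~batch.missing_mask
    if bad.to_numpy().any():
        met = bad.any(axis=1)
        met_id = met[met].index[0]
        meas = bad.loc[met_id]
        meas_id = meas[meas].index[0]
        raise PreprocessError(
            f"non-positive signal for metabolite {met_id!r} at measurement "
            f"{meas_id!r}; cannot log2 transform"
        )
    return batch.copy_with(values=np.log2(vals), scale="log2")


def presence_filter(
    batches: list[AssayBatch], min_presence: float = 0.5
) -> tuple[list[AssayBatch], list[str]]:
    """Drop metabolites observed in fewer than ``min_presence`` of all
    measurements, pooled across batches.

    Presence means the entry is not missing.  Metabolite order is preserved;
    the second return value lists the dropped metabolite ids.  Idempotent.
    """
    if not batches:
        return [], []
    mets = batches[0].values.index
    for b in batches[1:]:
        if not b.values.index.equals(mets):
            raise PreprocessError("presence_filter: inconsistent metabolite ordering")
    observed = sum((~b.missing_mask).sum(axis=1) for b in batches)
    total = sum(b.n_measurements for b in batches)
    frac = observed / total
    keep = frac >= min_presence
    dropped = list(mets[~keep])
    if not keep.any():
        logger.warning("presence_filter: no metabolite passes the %.0f%% "
                       "threshold", 100 * min_presence)
    out = [b.subset_metabolites(mets[keep]) for b in batches]
    return out, dropped


def knn_impute(batch: AssayBatch, k: int = 10) -> AssayBatch:
    """Impute missing entries by k-nearest-neighbour averaging.

    Neighbours are measurements (samples); distance is the NaN-aware
    Euclidean distance over shared observed metabolites and contributions
    are weighted by inverse distance.  Observed entries are never altered
    and the original missing mask is preserved for later restoration.
    """
    if batch.scale != "log2":
        raise PreprocessError("knn_impute expects log2-scale data")
    vals = batch.values
    if not vals.isna().to_numpy().any():
        return batch.copy_with()
    all_missing_met = vals.isna().all(axis=1)
    if all_missing_met.any():
        raise PreprocessError(
            f"metabolite {all_missing_met[all_missing_met].index[0]!r} has no "
            "observed value; cannot impute"
        )
    all_missing_meas = vals.isna().all(axis=0)
    if all_missing_meas.any():
        raise PreprocessError(
            f"measurement {all_missing_meas[all_missing_meas].index[0]!r} has "
            "no observed value; cannot impute"
        )
    k_eff = min(k, vals.shape[1] - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance")
    filled = imputer.fit_transform(vals.T.to_numpy())  # samples x metabolites
    out_vals = pd.DataFrame(filled.T, index=vals.index, columns=vals.columns)
    if np.isnan(filled).any():  # pragma: no cover - KNNImputer guarantees fill
        raise PreprocessError("imputation left missing entries")
    return batch.copy_with(values=out_vals)


def restore_missing(batch: AssayBatch) -> AssayBatch:
    """Reset entries that were missing on input back to ``NaN``.

    The complement of the mask is untouched, so this is the exact inverse of
    imputation on originally-missing coordinates.
    """
    mask = batch.missing_mask
    if mask.shape != batch.values.shape:
        raise PreprocessError("restore_missing: mask shape mismatch")
    vals = batch.values.mask(mask)
    return batch.copy_with(values=vals)


def qc_outlier_screen(
    batch: AssayBatch, z_threshold: float = 3.5
) -> tuple[AssayBatch, pd.DataFrame]:
    """Drop conditioning-QC injections that are outliers against the batch's
    pooled-QC injections.

    Each QC injection is summarised by its median signal across metabolites;
    a conditioning QC whose robust z-score — deviation from the pooled-QC
    median in units of 1.4826x their median absolute deviation — exceeds
    ``z_threshold`` is removed.  Returns the screened batch and a report of
    removals (measurement id, summary, z).
    """
    ann = batch.annotation
    cond = ann.index[ann["sample_type"] == "conditioningQC"]
    pooled = ann.index[ann["sample_type"] == "pooledQC"]
    report = pd.DataFrame(columns=["measurement", "summary", "z"]).set_index(
        "measurement"
    )
    if len(cond) == 0 or len(pooled) == 0:
        return batch.copy_with(), report
    pooled_summary = batch.values[pooled].median(axis=0, skipna=True)
    center = float(pooled_summary.median())
    mad = float((pooled_summary - center).abs().median())
    scale = 1.4826 * mad
    removed = []
    for m in cond:
        summary = float(batch.values[m].median(skipna=True))
        dev = abs(summary - center)
        if scale > 0:
            z = dev / scale
        else:
            z = np.inf if dev > 0 else 0.0
        if z > z_threshold:
            removed.append((m, summary, z))
    if removed:
        report = pd.DataFrame(
            removed, columns=["measurement", "summary", "z"]
        ).set_index("measurement")
        removed_ids = {m for m, _, _ in removed}
        keep = [m for m in batch.annotation.index if m not in removed_ids]
        logger.info("qc_outlier_screen: removed %d conditioning QC(s): %s",
                    len(removed), [m for m, _, _ in removed])
        return batch.subset_measurements(keep), report
    return batch.copy_with(), report


# ---------------------------------------------------------------------------
# matrix CSV I/O: first column metabolite id, remaining columns measurement
# ids matching the design sheet; missing encoded as empty cell or NA
# ---------------------------------------------------------------------------

def write_matrix_csv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, index_label="metabolite", na_rep="NA")


def read_matrix_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    frame.index.name = "metabolite"
    frame.columns = frame.columns.astype(str)
    return frame
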