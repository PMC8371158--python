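"""Quantitative assessment of normalisation quality.

The battery covers both sides of the normalisation trade-off: technical
replicates of one biological sample should agree (replicate SD), samples
should no longer cluster by batch (adjusted Rand index against batch
labels), per-sample distributions should be symmetric (skewness) and
centred (relative log expression), and run-order trends should be flat
(run series).  Operations return data tables; figure drawing is a thin
optional layer on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .preprocess import AssayBatch
from .ruv_core import ReplicateMap

__all__ = [
    "EvalReport",
    "EvaluationError",
    "replicate_sd",
    "skewness",
    "batch_ari",
    "rle_values",
    "run_series",
    "pca_scores",
    "evaluate",
]


class EvaluationError(ValueError):
    pass


def _values_and_annotation(assay) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    if isinstance(assay, AssayBatch):
        return assay.values, assay.annotation
    return pd.DataFrame(assay), None


def replicate_sd(assay, rep_map: ReplicateMap | None = None) -> pd.DataFrame:
    """Within-replicate-group sample standard deviation per metabolite.

    Groups come from ``rep_map`` or, if absent, from the assay annotation's
    ``replicate_group`` column.  Groups of size 1 are excluded; the result
    is metabolites x groups.  Invariant to adding a constant to a
    metabolite, and zero for identical replicates.
    """
    values, ann = _values_and_annotation(assay)
    if rep_map is not None:
        groups = pd.Series(
            np.array(rep_map.group_ids)[rep_map.indicator.argmax(axis=1)],
            index=values.columns,
        )
    elif ann is not None:
        groups = ann["replicate_group"]
    else:
        raise EvaluationError("replicate_sd needs a ReplicateMap or annotation")
    sizes = groups.value_counts()
    multi = sizes.index[sizes >= 2]
    if len(multi) == 0:
        raise EvaluationError("no replicate group with >= 2 members")
    out = {}
    for g in multi:
        cols = groups.index[groups == g]
        out[g] = values[cols].std(axis=1, ddof=1)
    return pd.DataFrame(out)


def skewness(sample_values) -> float:
    """Third-moment skewness m3 / s^3 of the non-missing values.

    m3 is the third central moment with an n denominator and s the sample
    standard deviation (n - 1 denominator).  Returns NaN for zero-variance
    input; fewer than 3 values raise.
    """
    x = np.asarray(pd.Series(sample_values).dropna(), dtype=float)
    n = x.size
    if n < 3:
        raise EvaluationError(f"skewness needs >= 3 non-missing values, got {n}")
    mu = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        return float("nan")
    m3 = np.mean((x - mu) ** 3)
    return float(m3 / s**3)


def batch_ari(
    assay,
    batch_labels=None,
    method: str = "kmeans",
    n_clusters: int | None = None,
    seed: int = 0,
    linkage: str = "complete",
) -> float:
    """Adjusted Rand index between a clustering of the samples and their
    batch labels.

    Samples are clustered on all metabolites into as many clusters as there
    are batches (k-means, or agglomerative with complete linkage).  Low
    values mean the batch signature has been removed.
    """
    values, ann = _values_and_annotation(assay)
    if batch_labels is None:
        if ann is None:
            raise EvaluationError("batch_ari needs batch labels or annotation")
        batch_labels = ann["batch"]
    batch_labels = np.asarray(pd.Series(batch_labels))
    if len(batch_labels) != values.shape[1]:
        raise EvaluationError("batch label length does not match measurements")
    n_batches = len(pd.unique(batch_labels))
    if n_batches < 2:
        raise EvaluationError("batch_ari needs >= 2 batches")
    if n_clusters is None:
        n_clusters = n_batches
    X = values.T.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise EvaluationError("batch_ari requires a complete matrix")
    if method == "kmeans":
        model = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    elif method == "hierarchical":
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage)
    else:
        raise EvaluationError("method must be 'kmeans' or 'hierarchical'")
    assignment = model.fit_predict(X)
    return float(adjusted_rand_score(batch_labels, assignment))


def rle_values(assay) -> pd.DataFrame:
    """Relative log expression: each entry minus its metabolite's median
    across samples.  Per-metabolite medians of the result are 0."""
    values, _ = _values_and_annotation(assay)
    med = values.median(axis=1, skipna=True)
    return values.sub(med, axis=0)


def run_series(assay, metabolite) -> pd.DataFrame:
    """(run_index, value) series for one metabolite, sorted by run order."""
    values, ann = _values_and_annotation(assay)
    if ann is None:
        raise EvaluationError("run_series needs an annotated assay")
    if metabolite not in values.index:
        raise EvaluationError(f"unknown metabolite {metabolite!r}")
    frame = pd.DataFrame(
        {
            "run_index": ann["run_index"].to_numpy(),
            "value": values.loc[metabolite].to_numpy(),
        },
        index=values.columns,
    )
    return frame.sort_values("run_index")


def pca_scores(assay, n_components: int = 2) -> pd.DataFrame:
    """First principal-component coordinates of each sample (centred, not
    scaled)."""
    values, _ = _values_and_annotation(assay)
    X = values.T.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise EvaluationError("pca_scores requires a complete matrix")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=values.columns, columns=cols)


@dataclass
class EvalReport:
    """Container for the assessment battery on one assay."""

    replicate_sd: pd.DataFrame
    skewness: pd.Series
    batch_ari: dict[str, float]
    rle: pd.DataFrame
    pca_scores: pd.DataFrame
    median_replicate_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.median_replicate_sd = float(
            np.nanmedian(self.replicate_sd.to_numpy())
        )

    def to_dict(self) -> dict:
        return {
            "median_replicate_sd": self.median_replicate_sd,
            "replicate_sd": {
                g: self.replicate_sd[g].dropna().to_dict()
                for g in self.replicate_sd.columns
            },
            "skewness": self.skewness.dropna().to_dict(),
            "batch_ari": self.batch_ari,
            "rle_sample_medians": self.rle.median(axis=0).to_dict(),
            "pca_scores": {
                c: self.pca_scores[c].to_dict() for c in self.pca_scores.columns
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(assay: AssayBatch, seed: int = 0) -> EvalReport:
    """Run the full battery on an annotated assay.

    Skewness is computed per sample over metabolites; ARI for both k-means
    and complete-linkage hierarchical clustering when >= 2 batches are
    present.
    """
    values = assay.values
    skew = pd.Series(
        {
            meas: (skewness(values[meas]) if values[meas].notna().sum() >= 3
                   else float("nan"))
            for meas in values.columns
        }
    )
    ari: dict[str, float] = {}
    complete = not values.isna().to_numpy().any()
    if assay.annotation["batch"].nunique() >= 2 and complete:
        for method in ("kmeans", "hierarchical"):
            ari[method] = batch_ari(assay, method=method, seed=seed)
    return EvalReport(
        replicate_sd=replicate_sd(assay),
        skewness=skew,
        batch_ari=ari,
        rle=rle_values(assay),
        pca_scores=pca_scores(assay) if complete else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# optional figure layer (matplotlib imported lazily)
# ---------------------------------------------------------------------------

def plot_rle(assay, ax=None):
    """RLE boxplot per sample; medians near zero indicate removed unwanted
    variation."""
    import matplotlib.pyplot as plt

    rle = rle_values(assay)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, rle.shape[1] * 0.12), 4))
    ax.boxplot([rle[c].dropna() for c in rle.columns], showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("sample (run order)")
    ax.set_ylabel("relative log expression")
    ax.set_xticks([])
    return ax


def plot_run(assay, metabolite, ax=None):
    """Scatter of one metabolite against run order; flat means no drift."""
    import matplotlib.pyplot as plt

    series = run_series(assay, metabolite)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(series["run_index"], series["value"], s=8)
    ax.set_xlabel("run order")
    ax.set_ylabel(f"log2 signal: {metabolite}")
    return ax


def plot_pca(assay, color_by: str = "batch", ax=None):
    """PC1 vs PC2 of the samples, coloured by an annotation column."""
    import matplotlib.pyplot as plt

    scores = pca_scores(assay)
    _, ann = _values_and_annotation(assay)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    groups = ann[color_by] if ann is not None else pd.Series(0, index=scores.index)
    for value, sub in scores.groupby(groups):
        ax.scatter(sub["PC1"], sub["PC2"], s=12, label=str(value))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(title=color_by, fontsize=7)
    return ax
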