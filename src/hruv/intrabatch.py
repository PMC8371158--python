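"""Within-batch signal-drift correction.

Instrument fouling and tuning changes make measured intensity drift with run
order, and each metabolite drifts differently.  Three families of correction
are provided:

* ``ratio`` — classical division of each raw signal by the nearest pooled-QC
  injection (earlier QC for the first half of the gap, later QC for the
  second half),
* smoothers — per metabolite, a loess curve or a robust linear fit against
  run order, fitted on all biological samples or on pooled QCs only; every
  measurement j is adjusted to y_ij + (median_i - fit_i(run_j)) so the batch
  median is preserved while the run-order trend is flattened,
* an optional replicate-anchored RUV step using the intra-batch short
  replicates, removing unwanted structure drift fitting cannot see.

Method tags follow the two-level grammar used throughout the package:
``loess``/``rlm`` fit pooled QCs, ``loessSample``/``rlmSample`` (equivalently
``loessAll``/``rlmAll``) fit biological samples, and a trailing ``Short``
appends the short-replicate RUV step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import BIOLOGICAL_TYPES, AssayBatch
from .ruv_core import ReplicateMap, adjust_group, build_replicate_matrix

__all__ = [
    "SmootherSpec",
    "IntrabatchError",
    "loess_smooth",
    "ratio_adjust",
    "smooth_adjust",
    "ruv_short",
    "run_intrabatch",
    "parse_intra_tag",
    "INTRA_TAGS",
]


class IntrabatchError(ValueError):
    pass


@dataclass(frozen=True)
class SmootherSpec:
    """Drift-smoother choice: loess or robust linear, fitted on all
    biological samples or on pooled QCs only."""

    kind: str  # loess | rlm
    scope: str = "all_samples"  # all_samples | pooled_qc
    span: float = 0.75
    max_iterations: int = 100
    degree: int = 2  # loess local-polynomial degree (pinned for reproducibility)

    def __post_init__(self) -> None:
        if self.kind not in ("loess", "rlm"):
            raise IntrabatchError("SmootherSpec.kind must be 'loess' or 'rlm'")
        if self.scope not in ("all_samples", "pooled_qc"):
            raise IntrabatchError(
                "SmootherSpec.scope must be 'all_samples' or 'pooled_qc'"
            )
        if not 0 < self.span <= 1:
            raise IntrabatchError("span must be in (0, 1]")
        if self.max_iterations < 1:
            raise IntrabatchError("max_iterations must be >= 1")


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``floor(span * n)`` nearest fitting points
    are weighted by tricube of distance scaled to the neighbourhood radius
    and a degree-``degree`` polynomial is fitted by weighted least squares
    (no robustifying iterations).  This is the classical local-regression
    recipe with span as the neighbourhood fraction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x.size
    if n < degree + 1:
        raise IntrabatchError(
            f"loess needs at least {degree + 1} points, got {n}"
        )
    q = int(np.floor(span * n))
    q = min(max(q, degree + 1), n)
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        radius = np.sort(d)[q - 1]
        if radius == 0:
            # q nearest points all coincide with x0: weighted mean of ties
            out[i] = y[d == 0].mean()
            continue
        u = d / radius
        w = np.clip(1 - u**3, 0, None) ** 3
        use = w > 0
        deg = degree
        while np.count_nonzero(use) < deg + 1 and deg > 0:
            deg -= 1
        xc = x[use] - x0
        X = np.vander(xc, deg + 1, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
        out[i] = beta[0]
    return out


def _rlm_fit(x: np.ndarray, y: np.ndarray, max_iterations: int) -> np.ndarray:
    """Huber M-estimated linear fit of y on run index; returns (intercept, slope)."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    model = sm.RLM(np.asarray(y, dtype=float), X, M=sm.robust.norms.HuberT())
    res = model.fit(maxiter=max_iterations)
    if not np.all(np.isfinite(res.params)):
        raise IntrabatchError("robust linear fit failed to converge")
    return res.params


def ratio_adjust(batch: AssayBatch) -> AssayBatch:
    """Divide each raw signal by its bracketing pooled-QC injection.

    With pooled QCs at runs L and L + M, measurements in (L, L + M/2] are
    divided by the earlier QC and those in (L + M/2, L + M] by the later
    one.  QC injections divide by themselves (ratio 1); measurements outside
    the QC span use the nearest QC.
    """
    if batch.scale != "raw":
        raise IntrabatchError(
            f"ratio adjustment requires raw-scale signals, got {batch.scale!r}"
        )
    ann = batch.annotation
    qc_ids = ann.index[ann["sample_type"] == "pooledQC"]
    if len(qc_ids) == 0:
        raise IntrabatchError("ratio adjustment needs pooled QC measurements")
    qc_runs = ann.loc[qc_ids, "run_index"].to_numpy()
    order = np.argsort(qc_runs)
    qc_runs = qc_runs[order]
    qc_ids = qc_ids[order]

    out = batch.values.copy()
    for meas in batch.values.columns:
        run = ann.loc[meas, "run_index"]
        pos = np.searchsorted(qc_runs, run)
        if run in qc_runs:
            ref = qc_ids[np.searchsorted(qc_runs, run)]
        elif pos == 0:
            ref = qc_ids[0]
        elif pos == len(qc_runs):
            ref = qc_ids[-1]
        else:
            L, nxt = qc_runs[pos - 1], qc_runs[pos]
            M = nxt - L
            ref = qc_ids[pos - 1] if run <= L + M / 2 else qc_ids[pos]
        ref_col = batch.values[ref]
        invalid = ref_col.isna() | (ref_col == 0)
        if invalid.any():
            met = invalid[invalid].index[0]
            raise IntrabatchError(
                f"pooled QC {ref!r} has zero/missing signal for metabolite "
                f"{met!r}; cannot form ratio"
            )
        out[meas] = batch.values[meas] / ref_col
    return batch.copy_with(values=out, scale="ratio")


def smooth_adjust(batch: AssayBatch, spec: SmootherSpec) -> AssayBatch:
    """Flatten per-metabolite run-order drift with a loess or robust linear
    fit, preserving each metabolite's batch median.

    The smoother is fitted, per metabolite, to the measurements in
    ``spec.scope`` (missing entries ignored) and evaluated at every
    measurement's run index; the adjustment adds (batch median - fitted
    value) to each entry.  Loess evaluation outside the fitted run span is
    clamped to the nearest fitted value.
    """
    if batch.scale != "log2":
        raise IntrabatchError("smooth_adjust expects log2-scale data")
    ann = batch.annotation
    if spec.scope == "pooled_qc":
        scope_ids = ann.index[ann["sample_type"] == "pooledQC"]
    else:
        scope_ids = ann.index[ann["sample_type"].isin(BIOLOGICAL_TYPES)]
    runs_all = ann["run_index"].to_numpy(dtype=float)
    out = batch.values.copy()
    for met in batch.values.index:
        y_scope = batch.values.loc[met, scope_ids]
        obs = y_scope.notna()
        x_fit = ann.loc[scope_ids[obs], "run_index"].to_numpy(dtype=float)
        y_fit = y_scope[obs].to_numpy(dtype=float)
        if x_fit.size < 4:
            raise IntrabatchError(
                f"metabolite {met!r}: only {x_fit.size} fitting points in "
                f"scope {spec.scope!r}, need >= 4"
            )
        if spec.kind == "loess":
            x_eval = np.clip(runs_all, x_fit.min(), x_fit.max())
            fitted = loess_smooth(
                x_fit, y_fit, x_eval, span=spec.span, degree=spec.degree
            )
        else:
            try:
                params = _rlm_fit(x_fit, y_fit, spec.max_iterations)
            except IntrabatchError as exc:
                raise IntrabatchError(f"metabolite {met!r}: {exc}") from exc
            fitted = params[0] + params[1] * runs_all
        med = float(np.nanmedian(batch.values.loc[met].to_numpy(dtype=float)))
        out.loc[met] = batch.values.loc[met].to_numpy() + (med - fitted)
    return batch.copy_with(values=out)


def short_replicate_map(
    batch: AssayBatch, include_qc: bool = False
) -> ReplicateMap:
    """Replicate map for intra-batch RUV: short-replicate groups are the
    only multi-member columns (optionally also the pooled-QC repeats);
    every other measurement is a singleton."""
    ann = batch.annotation
    short_groups = set(
        ann.loc[ann["sample_type"] == "shortReplicate", "replicate_group"]
    )
    labels = []
    for meas, rec in ann.iterrows():
        grp = rec["replicate_group"]
        is_qc = rec["sample_type"] in ("pooledQC", "conditioningQC")
        if grp in short_groups and rec["sample_type"] in BIOLOGICAL_TYPES:
            labels.append(grp)
        elif include_qc and is_qc:
            labels.append(grp)
        else:
            labels.append(f"__single__{meas}")
    return build_replicate_matrix(labels)


def ruv_short(
    batch: AssayBatch,
    k: int = 5,
    controls=None,
    include_qc: bool = False,
    k_policy: str = "cap",
) -> AssayBatch:
    """Remove unwanted intra-batch variation anchored on short replicates.

    Delegates to :func:`hruv.ruv_core.adjust_group` with a replicate map
    built from the batch's short-replicate groups (pooled-QC repeats are
    excluded by default; heterogeneous sample replicates estimate unwanted
    variation more robustly than repeats of a single pool).
    """
    if batch.values.isna().to_numpy().any():
        raise IntrabatchError("ruv_short requires a complete matrix; impute first")
    rep_map = short_replicate_map(batch, include_qc=include_qc)
    if not rep_map.replicated_groups():
        raise IntrabatchError(
            "no short-replicate pairs in this batch; skip the RUV step"
        )
    if k == 0:
        return batch.copy_with()
    Y = batch.values.T.to_numpy(dtype=float)  # measurements x metabolites
    adj = adjust_group(Y, rep_map, controls=controls, k=k, k_policy=k_policy)
    out = pd.DataFrame(adj.T, index=batch.values.index, columns=batch.values.columns)
    return batch.copy_with(values=out)


#: accepted intra-batch method tags
INTRA_TAGS = (
    "ratio",
    "loess",
    "rlm",
    "loessSample",
    "rlmSample",
    "loessAll",
    "rlmAll",
    "loessShort",
    "rlmShort",
    "loessSampleShort",
    "rlmSampleShort",
    "loessAllShort",
    "rlmAllShort",
)

_TAG_RE = re.compile(r"^(loess|rlm)(Sample|All)?(Short)?$")


@dataclass(frozen=True)
class IntraSpec:
    """Parsed intra-batch method: optional ratio/smoother plus RUV flag."""

    kind: str  # ratio | loess | rlm
    scope: str | None = None
    short_ruv: bool = False

    def smoother(self, span: float = 0.75, max_iterations: int = 100) -> SmootherSpec:
        if self.kind == "ratio":
            raise IntrabatchError("ratio method has no smoother")
        return SmootherSpec(
            kind=self.kind,
            scope=self.scope,
            span=span,
            max_iterations=max_iterations,
        )


def parse_intra_tag(tag: str) -> IntraSpec:
    """Parse an intra-batch tag like ``loessAllShort`` or ``rlm``.

    Bare ``loess``/``rlm`` fit pooled QCs only; a ``Sample``/``All`` infix
    fits all biological samples; a ``Short`` suffix adds short-replicate
    RUV.  ``ratio`` is the classical nearest-QC division.
    """
    if tag == "ratio":
        return IntraSpec(kind="ratio")
    m = _TAG_RE.match(tag)
    if not m:
        raise IntrabatchError(
            f"unknown intra-batch tag {tag!r}; valid tags: {', '.join(INTRA_TAGS)}"
        )
    kind, scope_tok, short = m.groups()
    scope = "all_samples" if scope_tok else "pooled_qc"
    return IntraSpec(kind=kind, scope=scope, short_ruv=bool(short))


def run_intrabatch(
    batch: AssayBatch,
    method_tag: str,
    k: int = 5,
    controls=None,
    span: float = 0.75,
    max_iterations: int = 100,
    include_qc: bool = False,
    k_policy: str = "cap",
) -> AssayBatch:
    """Apply the intra-batch correction named by ``method_tag``."""
    spec = parse_intra_tag(method_tag)
    if spec.kind == "ratio":
        return ratio_adjust(batch)
    out = smooth_adjust(batch, spec.smoother(span=span, max_iterations=max_iterations))
    if spec.short_ruv:
        out = ruv_short(
            out, k=k, controls=controls, include_qc=include_qc, k_policy=k_policy
        )
    return out
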