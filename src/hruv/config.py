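"""Pipeline configuration and end-to-end wiring.

The empty configuration reproduces the reference pipeline: log2 transform,
50% presence filter, k = 10 nearest-neighbour imputation, conditioning-QC
outlier screen, ``loessAllShort`` intra-batch correction (loess span 0.75
on all biological samples followed by short-replicate RUV with k = 5), a
concatenating merge tree with batch-replicate-anchored RUV (k = 5) at every
merge, and restoration of originally-missing entries at the end.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from . import evaluation, hierarchy, intrabatch, preprocess, ruv_core
from .preprocess import AssayBatch

logger = logging.getLogger("hruv")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """End-to-end settings; defaults are the reference pipeline."""

    method_tag: str = "loessAllShort_batch_Hc"
    k: int = 5
    k_policy: str = "cap"  # cap | error
    controls: str | list = "all"  # all | adaptive | explicit metabolite list
    n_controls: int | None = None  # for adaptive selection
    min_presence: float = 0.5
    impute_k: int = 10
    loess_span: float = 0.75
    rlm_max_iter: int = 100
    qc_outlier_z: float = 3.5
    drop_conditioning_qc: bool = True
    include_qc_replicates: bool = False
    replicate_policy: str = "all"  # all | cross_only
    restore_missing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # validate the tag eagerly so misconfiguration fails before data I/O
        hierarchy.parse_method_tag(self.method_tag)
        if self.k < 0:
            raise PipelineError("k must be >= 0")
        if self.k_policy not in ("cap", "error"):
            raise PipelineError("k_policy must be 'cap' or 'error'")
        if not 0 <= self.min_presence <= 1:
            raise PipelineError("min_presence must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _resolve_controls(config: PipelineConfig, batches, phenotype, mets):
    if isinstance(config.controls, (list, tuple)):
        idx = [i for i, m in enumerate(mets) if m in set(config.controls)]
        if not idx:
            raise PipelineError("none of the listed control metabolites found")
        return idx
    if config.controls == "all":
        return None
    if config.controls == "adaptive":
        if phenotype is None:
            raise PipelineError("adaptive control selection needs a phenotype")
        n = config.n_controls or max(1, int(0.8 * len(mets)))
        chosen = ruv_core.select_negative_controls(batches, phenotype, n)
        return [i for i, m in enumerate(mets) if m in set(chosen)]
    raise PipelineError(f"unknown controls setting {config.controls!r}")


def run_pipeline(
    config: PipelineConfig,
    batches: list[AssayBatch],
    phenotype=None,
) -> tuple[AssayBatch, evaluation.EvalReport, list[dict]]:
    """Preprocess, intra-batch correct, hierarchically merge and evaluate.

    ``batches`` may be raw scale (log2 applied here) or already log2.
    Returns the single merged assay, the evaluation report, and the
    structured merge log (from which the executed tree can be
    reconstructed).  Deterministic given inputs and config.
    """
    if not batches:
        raise PipelineError("no input batches")
    intra_spec, strategy = hierarchy.parse_method_tag(config.method_tag)

    stage = "preprocess"
    try:
        if intra_spec.kind == "ratio":
            if any(b.scale != "raw" for b in batches):
                raise PipelineError("ratio adjustment requires raw-scale input")
            batches = [intrabatch.ratio_adjust(b) for b in batches]
            # ratios are dimensionless and positive; continue on log2 scale
            batches = [
                b.copy_with(values=b.values, scale="raw") for b in batches
            ]
            batches = [preprocess.log2_transform(b) for b in batches]
        elif any(b.scale == "raw" for b in batches):
            batches = [
                preprocess.log2_transform(b) if b.scale == "raw" else b
                for b in batches
            ]
        batches, dropped = preprocess.presence_filter(
            batches, config.min_presence
        )
        if dropped:
            logger.info("presence filter dropped %d metabolites: %s",
                        len(dropped), dropped)
        screened = []
        for b in batches:
            b, report = preprocess.qc_outlier_screen(b, config.qc_outlier_z)
            if config.drop_conditioning_qc:
                keep = b.annotation.index[
                    b.annotation["sample_type"] != "conditioningQC"
                ]
                b = b.subset_measurements(keep)
            screened.append(b)
        batches = [preprocess.knn_impute(b, config.impute_k) for b in screened]

        mets = list(batches[0].values.index)
        controls = _resolve_controls(config, batches, phenotype, mets)

        stage = "intrabatch"
        if intra_spec.kind != "ratio":
            adjusted = []
            for b in batches:
                out = intrabatch.smooth_adjust(
                    b,
                    intra_spec.smoother(
                        span=config.loess_span,
                        max_iterations=config.rlm_max_iter,
                    ),
                )
                if intra_spec.short_ruv:
                    out = intrabatch.ruv_short(
                        out,
                        k=config.k,
                        controls=controls,
                        include_qc=config.include_qc_replicates,
                        k_policy=config.k_policy,
                    )
                adjusted.append(out)
            batches = adjusted
        elif intra_spec.short_ruv:
            batches = [
                intrabatch.ruv_short(
                    b, k=config.k, controls=controls,
                    include_qc=config.include_qc_replicates,
                    k_policy=config.k_policy,
                )
                for b in batches
            ]

        stage = "hierarchy"
        merge_log: list[dict] = []
        if strategy is not None and len(batches) > 1:
            ids = [b.annotation["batch"].iloc[0] for b in batches]
            plan = hierarchy.plan_for_strategy(ids, strategy)
            merged, merge_log = hierarchy.execute_plan(
                batches,
                plan,
                k=config.k,
                controls=controls,
                replicate_policy=config.replicate_policy,
                include_qc=config.include_qc_replicates,
                k_policy=config.k_policy,
            )
        elif len(batches) > 1:
            import pandas as pd

            merged = AssayBatch(
                values=pd.concat([b.values for b in batches], axis=1),
                annotation=pd.concat([b.annotation for b in batches], axis=0),
                scale=batches[0].scale,
                missing_mask=pd.concat(
                    [b.missing_mask for b in batches], axis=1
                ),
            )
        else:
            merged = batches[0]

        stage = "postprocess"
        if config.restore_missing:
            merged = preprocess.restore_missing(merged)

        stage = "evaluation"
        report = evaluation.evaluate(merged, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return merged, report, merge_log
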