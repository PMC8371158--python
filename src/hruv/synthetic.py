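"""Synthetic multi-batch metabolomics experiments with known ground truth.

The generator lays samples out with the replicate-embedding design, then
builds each measured log2 intensity additively:

    observed = biology(sample) + drift(metabolite, batch, run)
             + batch_offset(metabolite, batch) + noise

Biology is fixed per biological sample, so every technical replicate of a
sample shares its biology and differs only through the technical terms at
its own run position — exactly the assumption the replicate-anchored
adjustment exploits.  Drift is per metabolite and per batch (linear, or
"smooth": linear + quadratic + one sinusoid, emulating the heterogeneous
curve shapes real metabolites show); batch offsets are additive per
(metabolite, batch); noise is i.i.d. Gaussian on the log2 scale; missing
entries are injected completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignConfig, DesignSheet, generate_design
from .preprocess import AssayBatch

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "truth_metrics",
           "standard_config"]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Defaults describe a targeted plasma panel: 100 metabolites with baseline
    log2 abundances ~ N(20, 2^2), between-individual biological variation of
    0.5 log2 units, smooth per-batch drift of roughly one log2 unit across a
    batch, factor-structured batch shifts of per-entry SD 1.5 (batch jumps of
    a few log2 units are routine in protracted acquisitions), per-injection
    correlated technical jitter of per-entry SD 0.2 (spray/injection
    fluctuations scale many analytes at once) plus independent residual
    noise of SD 0.1 (~7% CV, the irreducible part of a well-integrated
    targeted assay), and a binary phenotype carried by 39% of individuals
    shifting 10% of metabolites by 0.5 log2 units (metabolite-phenotype
    associations are typically subtle, well under 1.5-fold).

    Unwanted variation is factor-structured: ``n_unwanted_factors`` latent
    technical causes (source fouling, tuning, temperature, spray state ...)
    have fixed metabolite loadings shared across batches, and every
    measurement receives a score on each factor that decomposes into a
    batch-level mean (the batch shift), a smooth within-batch trajectory
    (the drift) and per-injection jitter.  Each metabolite's drift is its
    loading-weighted mixture of the factor profiles, so drift shapes are
    heterogeneous across metabolites while the variation of the whole batch
    is low-dimensional — matching what principal components of raw LC-MS
    batches show (a run-order gradient along the top components).  Setting
    ``n_unwanted_factors = 0`` draws independent offsets, drift curves and
    jitter per metabolite instead.
    """

    design: DesignConfig
    n_metabolites: int = 100
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    biological_sd: float = 0.5
    drift: str = "smooth"  # none | linear | smooth
    drift_slope_sd: float = 1.0
    drift_smooth_amplitude: float = 0.5
    batch_shift_sd: float = 1.5
    technical_jitter_sd: float = 0.2
    n_unwanted_factors: int = 5
    phenotype_fraction: float = 0.39
    n_affected: int = 10
    effect_size: float = 0.5
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "biological_sd", "drift_slope_sd",
                     "drift_smooth_amplitude", "batch_shift_sd",
                     "technical_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")
        if not 0 <= self.phenotype_fraction <= 1:
            raise SyntheticError("phenotype_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise SyntheticError("missing_rate must be in [0, 1)")
        if self.n_affected > self.n_metabolites:
            raise SyntheticError("n_affected cannot exceed n_metabolites")
        if self.drift not in ("none", "linear", "smooth"):
            raise SyntheticError("drift must be 'none', 'linear' or 'smooth'")
        if self.n_unwanted_factors < 0:
            raise SyntheticError("n_unwanted_factors must be >= 0")


def standard_config(seed: int = 0, n_batches: int = 6, **overrides) -> SimConfig:
    """The reference scenario used throughout the test bed: ``n_batches``
    trays of the 8 x 11 geometry with 5 inter-batch replicates, and the
    default drift / batch-shift / biology settings."""
    design = DesignConfig(
        n_batches=n_batches,
        rows_per_batch=8,
        row_size=11,
        n_batch_replicates=5,
        n_conditioning_qc=3,
        seed=seed,
    )
    return SimConfig(design=design, seed=seed, **overrides)


@dataclass
class SimTruth:
    """Ground truth emitted next to the observed batches."""

    drift_curves: pd.DataFrame  # metabolites x all measurements
    batch_offsets: pd.DataFrame  # metabolites x batch id
    affected_set: list[str]
    phenotype: pd.Series  # per biological sample (individuals)
    clean_signal: pd.DataFrame  # metabolites x all measurements, biology only
    sheet: DesignSheet = field(repr=False, default=None)


def _drift_profiles(
    config: SimConfig, rng: np.random.Generator, pos: np.ndarray, n: int
) -> np.ndarray:
    """``n`` random drift profiles evaluated at normalised run positions
    pos in [-0.5, 0.5]: a linear ramp, optionally plus a quadratic bow and
    one sinusoid ("smooth")."""
    curves = np.zeros((n, pos.size))
    if config.drift == "none":
        return curves
    slope = rng.normal(0.0, config.drift_slope_sd, size=n)
    curves += slope[:, None] * pos[None, :]
    if config.drift == "smooth":
        quad = rng.normal(0.0, config.drift_smooth_amplitude, size=n)
        amp = rng.normal(0.0, config.drift_smooth_amplitude, size=n)
        freq = rng.integers(1, 3, size=n)
        phase = rng.uniform(0.0, 2 * np.pi, size=n)
        curves += quad[:, None] * (pos[None, :] ** 2 - 1 / 12)
        curves += amp[:, None] * np.sin(
            2 * np.pi * freq[:, None] * pos[None, :] + phase[:, None]
        )
    return curves


def _drift_matrix(
    config: SimConfig,
    rng: np.random.Generator,
    pos: np.ndarray,
    loadings: np.ndarray | None,
) -> np.ndarray:
    """Per-metabolite drift for one batch.

    With factor structure, each metabolite's curve is its loading-weighted
    mixture of the batch's per-factor temporal profiles; the sqrt(M/F)
    scaling keeps the per-entry drift magnitude at the profile scale.
    """
    if config.drift == "none":
        return np.zeros((config.n_metabolites, pos.size))
    if loadings is None:
        return _drift_profiles(config, rng, pos, config.n_metabolites)
    profiles = _drift_profiles(config, rng, pos, loadings.shape[0])
    scale = np.sqrt(config.n_metabolites / loadings.shape[0])
    return scale * (loadings.T @ profiles)


def simulate_experiment(config: SimConfig) -> tuple[list[AssayBatch], SimTruth]:
    """Generate per-batch log2 assay matrices plus the ground truth.

    Deterministic for a fixed ``config.seed`` (the design's own seed lives
    in ``config.design.seed``).  Returned batches are log2 scale with
    missing entries as NaN.
    """
    sheet = generate_design(config.design)
    rng = np.random.default_rng(config.seed)
    ann = sheet.annotation()
    met_ids = [f"M{i + 1:03d}" for i in range(config.n_metabolites)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_metabolites)
    affected_idx = rng.choice(config.n_metabolites, size=config.n_affected,
                              replace=False)
    affected = np.zeros(config.n_metabolites, dtype=bool)
    affected[affected_idx] = True

    # biology per distinct biological sample; the pooled QC is the mixture
    # expectation of the cohort
    individuals = sorted(
        ann.loc[ann["sample_type"] == "individual", "replicate_group"].unique()
    )
    phenotype = pd.Series(
        (rng.random(len(individuals)) < config.phenotype_fraction).astype(int),
        index=individuals,
    )
    biology: dict[str, np.ndarray] = {}
    for sid in individuals:
        b = baseline + rng.normal(0.0, config.biological_sd,
                                  size=config.n_metabolites)
        if phenotype[sid]:
            b = b + config.effect_size * affected
        biology[sid] = b
    biology["QC"] = baseline + config.phenotype_fraction * config.effect_size * affected

    # shared metabolite loadings of the latent technical factors behind both
    # the batch shifts and the drift; scores/profiles are redrawn per batch
    loadings = None
    if config.n_unwanted_factors > 0:
        loadings = rng.normal(size=(config.n_unwanted_factors,
                                    config.n_metabolites))
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        factor_scale = np.sqrt(
            config.n_metabolites / config.n_unwanted_factors
        )
        shift_scale = config.batch_shift_sd * factor_scale
        jitter_scale = config.technical_jitter_sd * factor_scale

    batches: list[AssayBatch] = []
    drift_cols, clean_cols = {}, {}
    offsets = {}
    batch_ids = sorted(ann["batch"].unique())
    for b in batch_ids:
        sub = ann[ann["batch"] == b]
        runs = sub["run_index"].to_numpy(dtype=float)
        span = runs.max() - runs.min()
        pos = (runs - runs.min()) / span - 0.5 if span > 0 else np.zeros_like(runs)
        drift = _drift_matrix(config, rng, pos, loadings)
        if loadings is not None:
            scores = rng.normal(size=config.n_unwanted_factors)
            offset = shift_scale * (scores @ loadings)
        else:
            offset = rng.normal(0.0, config.batch_shift_sd,
                                size=config.n_metabolites)
        offsets[b] = offset
        clean = np.column_stack(
            [biology[g] for g in sub["replicate_group"]]
        )
        if config.technical_jitter_sd > 0:
            if loadings is not None:
                jscores = rng.normal(
                    size=(config.n_unwanted_factors, clean.shape[1])
                )
                jitter = jitter_scale * (loadings.T @ jscores)
            else:
                jitter = rng.normal(0.0, config.technical_jitter_sd,
                                    size=clean.shape)
        else:
            jitter = np.zeros_like(clean)
        noise = rng.normal(0.0, config.noise_sd, size=clean.shape)
        observed = clean + drift + offset[:, None] + jitter + noise
        mask = rng.random(clean.shape) < config.missing_rate
        values = pd.DataFrame(observed, index=met_ids, columns=sub.index)
        values = values.mask(pd.DataFrame(mask, index=met_ids, columns=sub.index))
        batch = AssayBatch(
            values=values,
            annotation=sub.copy(),
            scale="log2",
            missing_mask=pd.DataFrame(mask, index=met_ids, columns=sub.index),
        )
        batches.append(batch)
        for j, meas in enumerate(sub.index):
            drift_cols[meas] = drift[:, j]
            clean_cols[meas] = clean[:, j]

    order = list(ann.index)
    truth = SimTruth(
        drift_curves=pd.DataFrame(drift_cols, index=met_ids)[order],
        batch_offsets=pd.DataFrame(offsets, index=met_ids),
        affected_set=[met_ids[i] for i in sorted(affected_idx)],
        phenotype=phenotype,
        clean_signal=pd.DataFrame(clean_cols, index=met_ids)[order],
        sheet=sheet,
    )
    return batches, truth


def truth_metrics(normalized, truth: SimTruth) -> dict:
    """Recovery report of a (normalised or raw) assay against the truth.

    * ``rmse`` — root-mean-square deviation from the clean biological
      signal after removing each metabolite's mean difference (a constant
      per-metabolite shift carries no information),
    * ``residual_drift_correlation`` — mean absolute Pearson correlation of
      the residual with run order, per (metabolite, batch),
    * ``residual_batch_offset`` — RMS of the per-(metabolite, batch) mean
      residuals after per-metabolite centring,
    * ``effect_retention`` — mean phenotype-group difference over the
      affected metabolites, to compare against the injected effect size.
    """
    values = normalized.values if isinstance(normalized, AssayBatch) else normalized
    ann = normalized.annotation if isinstance(normalized, AssayBatch) else None
    common = [c for c in values.columns if c in truth.clean_signal.columns]
    if not common:
        raise SyntheticError("no overlap between assay and truth measurement ids")
    if len(common) != values.shape[1]:
        raise SyntheticError("assay contains measurements unknown to the truth")
    vals = values[common]
    clean = truth.clean_signal[common]
    resid = vals - clean
    resid_centered = resid.sub(resid.mean(axis=1, skipna=True), axis=0)
    rmse = float(np.sqrt(np.nanmean(resid_centered.to_numpy() ** 2)))

    drift_corr = []
    offset_means = {}
    if ann is not None:
        for b, sub in ann.loc[common].groupby("batch"):
            runs = sub["run_index"].to_numpy(dtype=float)
            block = resid_centered[sub.index].to_numpy()
            offset_means[b] = np.nanmean(block, axis=1)
            if len(runs) >= 3:
                for row in block:
                    ok = ~np.isnan(row)
                    if ok.sum() >= 3 and np.nanstd(row[ok]) > 0:
                        drift_corr.append(
                            abs(np.corrcoef(runs[ok], row[ok])[0, 1])
                        )
    residual_drift = float(np.mean(drift_corr)) if drift_corr else float("nan")
    if offset_means:
        om = pd.DataFrame(offset_means)
        om = om.sub(om.mean(axis=1), axis=0)
        residual_offset = float(np.sqrt(np.nanmean(om.to_numpy() ** 2)))
    else:
        residual_offset = float("nan")

    effect = float("nan")
    if truth.affected_set and ann is not None:
        indiv = ann.loc[common]
        indiv = indiv[indiv["sample_type"] == "individual"]
        labels = indiv["replicate_group"].map(truth.phenotype)
        pos = indiv.index[labels == 1]
        neg = indiv.index[labels == 0]
        if len(pos) and len(neg):
            diffs = (
                vals.loc[truth.affected_set, pos].mean(axis=1)
                - vals.loc[truth.affected_set, neg].mean(axis=1)
            )
            effect = float(diffs.mean())

    return {
        "rmse": rmse,
        "residual_drift_correlation": residual_drift,
        "residual_batch_offset": residual_offset,
        "effect_retention": effect,
    }
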