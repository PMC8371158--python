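"""Replicate-embedding experimental design for multi-batch LC-MS runs.

A batch is an autosampler tray laid out as a grid of ``rows_per_batch`` rows
by ``row_size`` positions.  Each row carries one pooled-QC injection (last
column) and otherwise individual study samples.  Three kinds of technical
replicates are embedded:

* **conditioning QCs** — pooled-QC injections run before the grid to settle
  the instrument; excluded from normalization by default,
* **short replicates** — from the second row onward, one individual sample
  from an earlier row of the same batch is re-injected at a random position
  in the current row,
* **batch replicates** — a random selection of individual samples from the
  immediately preceding batch, re-injected at the start of the next batch.

Short replicates capture technical variation over ~10 runs; batch replicates
link consecutive batches and anchor inter-batch removal of unwanted
variation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "DesignEntry",
    "DesignSheet",
    "DesignSummary",
    "generate_design",
    "summarize_design",
    "write_design_csv",
    "read_design_csv",
    "SAMPLE_TYPES",
]

#: valid values of ``DesignEntry.sample_type``
SAMPLE_TYPES = (
    "individual",
    "pooledQC",
    "conditioningQC",
    "shortReplicate",
    "batchReplicate",
)

#: replicate-group label shared by every pooled/conditioning QC injection
QC_GROUP = "QC"

DESIGN_COLUMNS = [
    "batch",
    "run_index",
    "row",
    "column",
    "sample_id",
    "sample_type",
    "replicate_group",
]


class DesignError(ValueError):
    """Raised for infeasible design configurations or malformed sheets."""


@dataclass(frozen=True)
class DesignConfig:
    """Geometry and replicate counts of a multi-batch acquisition.

    Parameters
    ----------
    n_batches:
        Number of batches (trays) in the study.
    rows_per_batch:
        Rows per tray (default 8).
    row_size:
        Injections per row, counting the pooled QC (default 11 = 10
        individual samples + 1 pooled QC).
    n_batch_replicates:
        Individual samples of batch *b* re-injected at the start of batch
        *b+1* (default 5).
    n_conditioning_qc:
        Pooled-QC injections run before each tray to condition the
        instrument (default 3).
    seed:
        Seed of the random stream that selects replicate sources and
        positions.
    short_replicate_source:
        ``"any_earlier"`` draws the short-replicate source from any earlier
        row of the batch (default); ``"previous_row"`` restricts to the
        immediately preceding row.
    scatter_batch_replicates:
        When True, batch replicates are placed at random grid positions
        rather than in a contiguous block at the start of the tray.
    stratify_batch_replicates:
        When True, batch-replicate sources are drawn evenly from the first
        and second halves (by row) of the previous batch, avoiding the
        chance clustering that plagues fully random selection.
    """

    n_batches: int
    rows_per_batch: int = 8
    row_size: int = 11
    n_batch_replicates: int = 5
    n_conditioning_qc: int = 3
    seed: int = 0
    short_replicate_source: str = "any_earlier"
    scatter_batch_replicates: bool = False
    stratify_batch_replicates: bool = False

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise DesignError("n_batches must be >= 1")
        if self.rows_per_batch < 1:
            raise DesignError("rows_per_batch must be >= 1")
        if self.row_size < 2:
            raise DesignError("row_size must be >= 2 (>=1 individual + 1 pooled QC)")
        for name in ("n_batch_replicates", "n_conditioning_qc"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.short_replicate_source not in ("any_earlier", "previous_row"):
            raise DesignError(
                "short_replicate_source must be 'any_earlier' or 'previous_row'"
            )
        n_grid_individual_slots = self.rows_per_batch * (self.row_size - 1)
        if self.n_batch_replicates >= n_grid_individual_slots:
            raise DesignError(
                "n_batch_replicates must be smaller than the number of "
                "individual-sample slots per batch"
            )


@dataclass(frozen=True)
class DesignEntry:
    """One injection of the run-order sheet."""

    batch: int
    run_index: int
    row: int
    column: int
    sample_id: str
    sample_type: str
    replicate_group: str


@dataclass
class DesignSheet:
    """Ordered run sheet: a list of :class:`DesignEntry` in acquisition order."""

    entries: list[DesignEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, DesignSheet) and self.entries == other.entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries], columns=DESIGN_COLUMNS
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DesignSheet":
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise DesignError(f"design sheet missing columns: {missing}")
        entries = []
        seen_runs: dict[int, int] = {}
        for pos, rec in enumerate(frame.itertuples(index=False)):
            try:
                entry = DesignEntry(
                    batch=int(rec.batch),
                    run_index=int(rec.run_index),
                    row=int(rec.row),
                    column=int(rec.column),
                    sample_id=str(rec.sample_id),
                    sample_type=str(rec.sample_type),
                    replicate_group=str(rec.replicate_group),
                )
            except (TypeError, ValueError) as exc:
                raise DesignError(f"malformed design row {pos + 1}: {exc}") from exc
            if entry.sample_type not in SAMPLE_TYPES:
                raise DesignError(
                    f"design row {pos + 1}: unknown sample_type "
                    f"{entry.sample_type!r}"
                )
            if entry.run_index in seen_runs:
                raise DesignError(
                    f"design row {pos + 1}: duplicate run_index "
                    f"{entry.run_index} (first seen at row "
                    f"{seen_runs[entry.run_index] + 1})"
                )
            seen_runs[entry.run_index] = pos
            entries.append(entry)
        entries.sort(key=lambda e: e.run_index)
        return cls(entries)

    def measurement_ids(self) -> list[str]:
        """Unique per-injection identifiers, ``<sample_id>.r<run_index>``."""
        return [f"{e.sample_id}.r{e.run_index}" for e in self.entries]

    def annotation(self) -> pd.DataFrame:
        """Per-measurement annotation table indexed by measurement id."""
        frame = self.to_frame()
        frame.index = pd.Index(self.measurement_ids(), name="measurement")
        return frame


@dataclass(frozen=True)
class DesignSummary:
    n_measurements: int
    n_individual: int
    n_pooled_qc: int
    n_conditioning_qc: int
    short_replicate_pairs: int
    batch_replicate_pairs: int
    distinct_individual_samples: int
    distinct_short_replicated_samples: int
    distinct_batch_replicated_samples: int
    batch_replicate_measurements: int


def _select(rng: np.random.Generator, pool: Sequence, size: int = 1) -> list:
    """Seeded selection without replacement from an ordered pool."""
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(int(i) for i in idx)]


def generate_design(config: DesignConfig) -> DesignSheet:
    """Generate the replicate-embedding run sheet for ``config``.

    The layout per batch is: ``n_conditioning_qc`` conditioning QCs (row 0,
    outside the grid), then the grid in row-major acquisition order with one
    pooled QC closing every row.  From batch 2 onward the first
    ``n_batch_replicates`` individual slots re-inject samples drawn from the
    previous batch's individuals that were not short-replicated there.  From
    row 2 onward one slot per row re-injects an earlier-row individual of the
    same batch not yet short-replicated.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    entries: list[DesignEntry] = []
    run = 0
    sample_counter = 0
    R, C = config.rows_per_batch, config.row_size

    # per-batch bookkeeping used by the next batch's replicate selection
    prev_individuals: list[tuple[str, int]] = []  # (sample_id, row)
    prev_short_replicated: set[str] = set()

    for b in range(1, config.n_batches + 1):
        for c in range(1, config.n_conditioning_qc + 1):
            run += 1
            entries.append(
                DesignEntry(b, run, 0, c, QC_GROUP, "conditioningQC", QC_GROUP)
            )

        # grid positions in acquisition order; pooled QC pinned to the last
        # column of each row
        grid = [(r, c) for r in range(1, R + 1) for c in range(1, C + 1)]
        assignment: dict[tuple[int, int], tuple[str, str, str]] = {}
        for r in range(1, R + 1):
            assignment[(r, C)] = (QC_GROUP, "pooledQC", QC_GROUP)
        open_slots = [p for p in grid if p not in assignment]

        # batch replicates: samples from the previous batch, re-injected at
        # the start of this one
        if b > 1 and config.n_batch_replicates > 0:
            candidates = [
                sid for sid, _ in prev_individuals if sid not in prev_short_replicated
            ]
            if len(candidates) < config.n_batch_replicates:
                raise DesignError(
                    f"batch {b}: only {len(candidates)} batch-replicate "
                    f"candidates in batch {b - 1}, "
                    f"{config.n_batch_replicates} requested"
                )
            if config.stratify_batch_replicates:
                half = (1 + R) / 2.0
                lo = [
                    sid
                    for sid, row in prev_individuals
                    if sid not in prev_short_replicated and row <= half
                ]
                hi = [
                    sid
                    for sid, row in prev_individuals
                    if sid not in prev_short_replicated and row > half
                ]
                n_lo = config.n_batch_replicates // 2 + config.n_batch_replicates % 2
                n_hi = config.n_batch_replicates - n_lo
                if len(lo) < n_lo or len(hi) < n_hi:
                    raise DesignError(
                        f"batch {b}: stratified batch-replicate selection "
                        "infeasible (one half of the previous batch is too small)"
                    )
                chosen = _select(rng, lo, n_lo) + _select(rng, hi, n_hi)
            else:
                chosen = _select(rng, candidates, config.n_batch_replicates)
            if config.scatter_batch_replicates:
                positions = _select(rng, open_slots, len(chosen))
            else:
                positions = open_slots[: len(chosen)]
            for sid, pos in zip(chosen, positions):
                assignment[pos] = (sid, "batchReplicate", sid)
                open_slots.remove(pos)

        # short replicates: one per row from the second row onward
        batch_individuals: list[tuple[str, int]] = []
        short_replicated: set[str] = set()
        for r in range(1, R + 1):
            row_slots = [p for p in open_slots if p[0] == r]
            if r >= 2:
                if config.short_replicate_source == "previous_row":
                    pool = [
                        sid
                        for sid, row in batch_individuals
                        if row == r - 1 and sid not in short_replicated
                    ]
                else:
                    pool = [
                        sid
                        for sid, row in batch_individuals
                        if row < r and sid not in short_replicated
                    ]
                if not pool:
                    raise DesignError(
                        f"batch {b}, row {r}: no eligible short-replicate "
                        "source in earlier rows"
                    )
                if not row_slots:
                    raise DesignError(
                        f"batch {b}, row {r}: no free position for the short "
                        "replicate"
                    )
                (src,) = _select(rng, pool, 1)
                (pos,) = _select(rng, row_slots, 1)
                assignment[pos] = (src, "shortReplicate", src)
                short_replicated.add(src)
                open_slots.remove(pos)
                row_slots.remove(pos)
            # remaining slots of this row are new individual samples
            for pos in row_slots:
                sample_counter += 1
                sid = f"S{sample_counter:04d}"
                assignment[pos] = (sid, "individual", sid)
                batch_individuals.append((sid, r))
                open_slots.remove(pos)

        for pos in grid:
            sid, stype, group = assignment[pos]
            run += 1
            entries.append(DesignEntry(b, run, pos[0], pos[1], sid, stype, group))

        prev_individuals = batch_individuals
        prev_short_replicated = short_replicated

    return DesignSheet(entries)


def summarize_design(sheet: DesignSheet) -> DesignSummary:
    """Count measurements, replicate pairs and distinct samples per category."""
    entries = sheet.entries
    by_type = {t: [e for e in entries if e.sample_type == t] for t in SAMPLE_TYPES}
    short_groups = {e.replicate_group for e in by_type["shortReplicate"]}
    batch_groups = {e.replicate_group for e in by_type["batchReplicate"]}
    batch_rep_measurements = sum(
        1
        for e in entries
        if e.replicate_group in batch_groups
        and e.sample_type in ("individual", "batchReplicate")
    )
    return DesignSummary(
        n_measurements=len(entries),
        n_individual=len(by_type["individual"]),
        n_pooled_qc=len(by_type["pooledQC"]),
        n_conditioning_qc=len(by_type["conditioningQC"]),
        short_replicate_pairs=len(by_type["shortReplicate"]),
        batch_replicate_pairs=len(by_type["batchReplicate"]),
        distinct_individual_samples=len({e.sample_id for e in by_type["individual"]}),
        distinct_short_replicated_samples=len(short_groups),
        distinct_batch_replicated_samples=len(batch_groups),
        batch_replicate_measurements=batch_rep_measurements,
    )


def write_design_csv(sheet: DesignSheet, path) -> None:
    """Write the run sheet as a headered UTF-8 CSV."""
    sheet.to_frame().to_csv(path, index=False)


def read_design_csv(path) -> DesignSheet:
    """Read a run sheet written by :func:`write_design_csv`.

    Raises :class:`DesignError` on malformed rows or duplicated run indices,
    naming the offending line.
    """
    try:
        frame = pd.read_csv(path, dtype={"sample_id": str, "replicate_group": str})
    except pd.errors.EmptyDataError as exc:
        raise DesignError(f"cannot parse design CSV {path}: {exc}") from exc
    return DesignSheet.from_frame(frame)
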