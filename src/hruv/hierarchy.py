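"""Hierarchical inter-batch integration.

Instead of estimating unwanted variation across all batches at once, batches
are merged pairwise along a binary tree, applying a replicate-anchored RUV
adjustment at every merge.  Two schedules are provided:

* **balanced** — neighbouring batches are paired, then neighbouring pairs,
  and so on; tree depth is ceil(log2 n) sequential rounds,
* **concatenating** — a left-deep chain that absorbs one batch at a time
  into the growing normalised set; appending m new batches later costs only
  m further adjustments.

Both schedules perform exactly n - 1 pairwise adjustments for n batches;
they differ in depth (number of sequential rounds), not in node count.
The batch replicates embedded by the design link consecutive batches, so
every merge union contains multi-member replicate groups to anchor RUV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intrabatch import IntraSpec, parse_intra_tag
from .preprocess import AssayBatch
from .ruv_core import adjust_group, build_replicate_matrix

logger = logging.getLogger("hruv")

__all__ = [
    "Merge",
    "MergePlan",
    "HierarchyError",
    "balanced_plan",
    "concat_plan",
    "execute_plan",
    "parse_method_tag",
]


class HierarchyError(ValueError):
    pass


@dataclass(frozen=True)
class Merge:
    """One pairwise adjustment: the two groups of batch ids it joins and the
    tree layer (sequential round) it belongs to."""

    left: tuple
    right: tuple
    layer: int

    @property
    def union(self) -> tuple:
        return self.left + self.right


@dataclass
class MergePlan:
    """Binary merge tree over batch ids."""

    batch_ids: tuple
    merges: list[Merge] = field(default_factory=list)
    strategy: str = "balanced"

    @property
    def n_merges(self) -> int:
        return len(self.merges)

    @property
    def depth(self) -> int:
        """Number of sequential adjustment rounds (tree depth)."""
        return max((m.layer for m in self.merges), default=0)


def balanced_plan(batch_ids) -> MergePlan:
    """Pair neighbouring batches, then neighbouring groups, layer by layer.

    An odd trailing group is carried unmerged into the next layer.  For n
    batches the plan holds n - 1 merges over ceil(log2 n) layers.
    """
    ids = tuple(batch_ids)
    if len(ids) < 1:
        raise HierarchyError("balanced_plan needs at least one batch")
    plan = MergePlan(batch_ids=ids, strategy="balanced")
    groups = [(b,) for b in ids]
    layer = 0
    while len(groups) > 1:
        layer += 1
        nxt = []
        for i in range(0, len(groups) - 1, 2):
            plan.merges.append(Merge(groups[i], groups[i + 1], layer))
            nxt.append(groups[i] + groups[i + 1])
        if len(groups) % 2:
            nxt.append(groups[-1])
        groups = nxt
    return plan


def concat_plan(batch_ids) -> MergePlan:
    """Left-deep chain ((...((1,2),3)...),n): n - 1 merges, depth n - 1."""
    ids = tuple(batch_ids)
    if len(ids) < 1:
        raise HierarchyError("concat_plan needs at least one batch")
    plan = MergePlan(batch_ids=ids, strategy="concatenating")
    acc = (ids[0],)
    for layer, b in enumerate(ids[1:], start=1):
        plan.merges.append(Merge(acc, (b,), layer))
        acc = acc + (b,)
    return plan


def _merge_replicate_labels(
    annotation: pd.DataFrame,
    left_ids,
    include_qc: bool,
    cross_only: bool,
) -> list[str]:
    """Per-measurement group labels for one merge.

    Multi-member replicate groups in the union anchor the adjustment; QC
    repeats are demoted to singletons unless ``include_qc``, and
    ``cross_only`` additionally demotes groups that do not span both sides
    of the merge.
    """
    groups = annotation["replicate_group"]
    is_qc = annotation["sample_type"].isin(["pooledQC", "conditioningQC"])
    sizes = groups.value_counts()
    left_set = set(left_ids)
    on_left = annotation["batch"].isin(left_set)
    labels = []
    for meas, grp in groups.items():
        keep = sizes[grp] >= 2
        if is_qc.loc[meas] and not include_qc:
            keep = False
        if keep and cross_only:
            members_left = on_left[groups == grp]
            keep = members_left.any() and (~members_left).any()
        labels.append(grp if keep else f"__single__{meas}")
    return labels


def execute_plan(
    batches: list[AssayBatch],
    plan: MergePlan,
    k: int = 5,
    controls=None,
    replicate_policy: str = "all",
    include_qc: bool = False,
    k_policy: str = "cap",
) -> tuple[AssayBatch, list[dict]]:
    """Run every merge of ``plan``, adjusting the concatenated pair at each
    step, and return the single merged assay plus a provenance log.

    ``replicate_policy`` selects which multi-member replicate groups anchor
    each merge: ``"all"`` uses every group with >= 2 members in the union
    (cross-batch links plus intra-batch leftovers); ``"cross_only"``
    restricts to groups spanning both sides.  The final output contains
    every input measurement exactly once, in plan order.
    """
    if replicate_policy not in ("all", "cross_only"):
        raise HierarchyError("replicate_policy must be 'all' or 'cross_only'")
    by_id: dict = {}
    for b in batches:
        bid = b.annotation["batch"].iloc[0]
        if (b.annotation["batch"] != bid).any():
            raise HierarchyError("each input AssayBatch must hold a single batch")
        by_id[bid] = b
    missing = [b for b in plan.batch_ids if b not in by_id]
    if missing:
        raise HierarchyError(f"plan references unknown batches {missing}")

    state: dict[tuple, AssayBatch] = {(b,): by_id[b] for b in plan.batch_ids}
    log: list[dict] = []
    for merge in plan.merges:
        left = state.pop(merge.left)
        right = state.pop(merge.right)
        if not left.values.index.equals(right.values.index):
            raise HierarchyError(
                f"merge {merge.left}+{merge.right}: metabolite sets differ"
            )
        values = pd.concat([left.values, right.values], axis=1)
        annotation = pd.concat([left.annotation, right.annotation], axis=0)
        mask = pd.concat([left.missing_mask, right.missing_mask], axis=1)
        if values.isna().to_numpy().any():
            raise HierarchyError(
                f"merge {merge.left}+{merge.right}: matrix has missing "
                "entries; impute before integration"
            )
        labels = _merge_replicate_labels(
            annotation, merge.left, include_qc, replicate_policy == "cross_only"
        )
        rep_map = build_replicate_matrix(labels)
        if not rep_map.replicated_groups():
            raise HierarchyError(
                f"merge {merge.left}+{merge.right}: no multi-member replicate "
                "group links the two sides"
            )
        k_used = min(k, rep_map.residual_rank)
        Y = values.T.to_numpy(dtype=float)
        adj = adjust_group(Y, rep_map, controls=controls, k=k, k_policy=k_policy)
        values = pd.DataFrame(adj.T, index=values.index, columns=values.columns)
        merged = AssayBatch(
            values=values, annotation=annotation, scale=left.scale, missing_mask=mask
        )
        state[merge.union] = merged
        record = {
            "layer": merge.layer,
            "left": merge.left,
            "right": merge.right,
            "n_measurements": values.shape[1],
            "n_replicate_groups": len(rep_map.replicated_groups()),
            "k_requested": k,
            "k_used": k_used,
            "k_capped": k_used < k,
        }
        log.append(record)
        logger.info(
            "merge layer %d: %s + %s (%d measurements, %d replicate groups, k=%d%s)",
            merge.layer, merge.left, merge.right, values.shape[1],
            record["n_replicate_groups"], k_used,
            " capped" if record["k_capped"] else "",
        )
    (final,) = state.values()
    return final, log


_METHOD_RE = re.compile(r"^(?P<intra>[A-Za-z]+)(_batch_(?P<tree>H|Hc))?$")


def parse_method_tag(tag: str) -> tuple[IntraSpec, str | None]:
    """Parse a full pipeline tag like ``loessAllShort_batch_Hc``.

    Grammar: ``<intra>[_batch_(H|Hc)]`` where ``<intra>`` is an intra-batch
    tag (``ratio``, ``loess[Sample|All][Short]``, ``rlm[Sample|All][Short]``),
    ``_batch_H`` requests the balanced tree and ``_batch_Hc`` the
    concatenating tree.  Returns the parsed intra spec and the tree strategy
    (``None`` for single-level tags).
    """
    m = _METHOD_RE.match(tag)
    if not m:
        raise HierarchyError(
            f"malformed method tag {tag!r}; expected "
            "'<smoother>[Sample|All][Short]' optionally followed by "
            "'_batch_H' (balanced tree) or '_batch_Hc' (concatenating tree)"
        )
    try:
        intra = parse_intra_tag(m.group("intra"))
    except Exception as exc:
        raise HierarchyError(f"malformed method tag {tag!r}: {exc}") from exc
    tree = m.group("tree")
    strategy = {"H": "balanced", "Hc": "concatenating", None: None}[tree]
    return intra, strategy


def plan_for_strategy(batch_ids, strategy: str) -> MergePlan:
    if strategy == "balanced":
        return balanced_plan(batch_ids)
    if strategy == "concatenating":
        return concat_plan(batch_ids)
    raise HierarchyError(f"unknown tree strategy {strategy!r}")
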