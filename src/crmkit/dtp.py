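"""Dose-transition pathways: exhaustive enumeration of cohort outcomes.

Every node is an enrolled cohort (index, assigned level); every branch is
one possible DLT count for that cohort together with the action the
escalation engine takes on the accumulated history — escalate, stay,
de-escalate, or one of the stop states.  The tree is used at the design
stage to audit the engine's behaviour and during conduct as a one-step
look-ahead table for the oversight committee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb

import pandas as pd

from .design import DesignSpec, ToxicityHistory
from .escalation import (
    CONTINUE,
    STOPPED_MAX_N,
    STOPPED_MTD_CONFIRMED,
    STOPPED_TOXIC,
    check_stopping,
)

__all__ = [
    "PathwayBranch",
    "PathwayNode",
    "enumerate_pathways",
    "next_cohort_table",
    "pathways_to_records",
    "pathways_to_dataframe",
    "pathways_to_json",
    "selection_distribution",
]


@dataclass(frozen=True)
class PathwayBranch:
    """One outcome of a cohort: its DLT count and the engine's action."""

    dlt_count: int
    action: str  # "escalate to L" | "stay" | "de-escalate to L" | stop states
    state: str  # engine state after this outcome
    next_level: int | None  # assignment of the next cohort, if continuing
    mtd_level: int | None  # declared MTD on stop (None on toxic stop)
    child: "PathwayNode | None"  # next cohort's node, if continuing in horizon


@dataclass(frozen=True)
class PathwayNode:
    """An enrolled cohort with all its outcome branches."""

    cohort_index: int  # 1-based
    dose_level: int  # 1-based
    branches: tuple[PathwayBranch, ...]


def _describe(state: str, current: int, nxt: int | None) -> str:
    if state == STOPPED_TOXIC:
        return "stop_toxic"
    if state == STOPPED_MTD_CONFIRMED:
        return "stop_mtd"
    if state == STOPPED_MAX_N:
        return "stop_max_n"
    if nxt > current:
        return f"escalate to {nxt}"
    if nxt < current:
        return f"de-escalate to {nxt}"
    return "stay"


def _expand(
    history: ToxicityHistory,
    level: int,
    cohort_index: int,
    n_cohorts: int,
    spec: DesignSpec,
) -> PathwayNode:
    branches = []
    for d in range(spec.cohort_size + 1):
        ext = history.extended(level, d, spec.cohort_size)
        status = check_stopping(ext, spec)
        action = _describe(status.state, level, status.recommended_level)
        child = None
        if status.state == CONTINUE and cohort_index < n_cohorts:
            child = _expand(
                ext, status.recommended_level, cohort_index + 1, n_cohorts, spec
            )
        branches.append(
            PathwayBranch(
                dlt_count=d,
                action=action,
                state=status.state,
                next_level=status.recommended_level,
                mtd_level=status.mtd_level,
                child=child,
            )
        )
    return PathwayNode(
        cohort_index=cohort_index, dose_level=level, branches=tuple(branches)
    )


def enumerate_pathways(spec: DesignSpec, n_cohorts: int) -> PathwayNode:
    """Enumerate all dose-transition pathways for the first ``n_cohorts`` cohorts.

    The root is the first cohort at the starting level; each branch's
    action is exactly what the escalation engine returns on the
    accumulated history, and stop branches are leaves.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    n_cohorts = min(n_cohorts, spec.max_cohorts)
    return _expand(ToxicityHistory(), spec.start_level, 1, n_cohorts, spec)


def next_cohort_table(history: ToxicityHistory, spec: DesignSpec) -> dict[int, dict]:
    """One-step look-ahead: action for every possible DLT count of the next cohort.

    The pending cohort is assigned per the engine; each row shows the
    recommendation or stop flag that its outcome would trigger.
    """
    status = check_stopping(history, spec)
    if status.state != CONTINUE:
        raise ValueError(f"trial already stopped ({status.state})")
    level = status.recommended_level
    table = {}
    for d in range(spec.cohort_size + 1):
        ext = history.extended(level, d, spec.cohort_size)
        after = check_stopping(ext, spec)
        table[d] = {
            "dose_level": level,
            "action": _describe(after.state, level, after.recommended_level),
            "state": after.state,
            "next_level": after.recommended_level,
            "mtd_level": after.mtd_level,
        }
    return table


def pathways_to_records(
    root: PathwayNode,
    spec: DesignSpec,
    scenario=None,
) -> list[dict]:
    """Flatten the tree to one record per (node, outcome branch).

    With a scenario, each record carries the probability of the path from
    the root through that branch (product of binomial cohort outcome
    probabilities under the scenario's true DLT curve).
    """
    records: list[dict] = []

    def prob_of(level: int, d: int) -> float:
        p = scenario.true_probs[level - 1]
        n = spec.cohort_size
        return comb(n, d) * p**d * (1.0 - p) ** (n - d)

    def walk(node: PathwayNode, path: str, prob: float) -> None:
        for br in node.branches:
            branch_path = f"{path}/{node.dose_level}:{br.dlt_count}"
            branch_prob = prob * prob_of(node.dose_level, br.dlt_count) if scenario else None
            records.append(
                {
                    "path": branch_path.lstrip("/"),
                    "cohort": node.cohort_index,
                    "dose_level": node.dose_level,
                    "dlt_count": br.dlt_count,
                    "action": br.action,
                    "state": br.state,
                    "next_level": br.next_level,
                    "mtd_level": br.mtd_level,
                    **({"path_prob": branch_prob} if scenario else {}),
                }
            )
            if br.child is not None:
                walk(br.child, branch_path, branch_prob if scenario else 1.0)

    walk(root, "", 1.0)
    return records


def pathways_to_dataframe(root: PathwayNode, spec: DesignSpec, scenario=None) -> pd.DataFrame:
    return pd.DataFrame(pathways_to_records(root, spec, scenario))


def pathways_to_json(root: PathwayNode, indent: int | None = 2) -> str:
    def encode(node: PathwayNode) -> dict:
        return {
            "cohort": node.cohort_index,
            "dose_level": node.dose_level,
            "branches": [
                {
                    "dlt_count": br.dlt_count,
                    "action": br.action,
                    "state": br.state,
                    "next_level": br.next_level,
                    "mtd_level": br.mtd_level,
                    "child": encode(br.child) if br.child is not None else None,
                }
                for br in node.branches
            ],
        }

    return json.dumps(encode(root), indent=indent)


def selection_distribution(spec: DesignSpec, scenario) -> tuple[tuple[float, ...], float]:
    """Exact MTD selection distribution by full-horizon pathway enumeration.

    Walks every pathway to the design's maximum number of cohorts,
    weighting branches by binomial outcome probabilities under the
    scenario.  Returns per-level selection probabilities and the
    no-selection (toxic stop) mass; an analytic counterpart of
    :func:`crmkit.simulate.simulate_oc`'s Monte-Carlo selection
    distribution.
    """
    root = enumerate_pathways(spec, spec.max_cohorts)
    sel = [0.0] * spec.n_levels
    no_sel = 0.0

    def prob_of(level: int, d: int) -> float:
        p = scenario.true_probs[level - 1]
        n = spec.cohort_size
        return comb(n, d) * p**d * (1.0 - p) ** (n - d)

    def walk(node: PathwayNode, prob: float) -> None:
        nonlocal no_sel
        for br in node.branches:
            q = prob * prob_of(node.dose_level, br.dlt_count)
            if br.state == STOPPED_TOXIC:
                no_sel += q
            elif br.state in (STOPPED_MTD_CONFIRMED, STOPPED_MAX_N):
                sel[br.mtd_level - 1] += q
            elif br.child is not None:
                walk(br.child, q)
            else:  # continuing branch at the enumeration horizon
                raise RuntimeError("enumeration horizon shorter than the design")

    walk(root, 1.0)
    return tuple(sel), no_sel
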