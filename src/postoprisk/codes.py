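"""Hierarchical aggregation of 4-digit surgical procedure codes.

ICD-9-CM procedure codes ("81.54") are prefix-hierarchical: the first two
digits name a broad procedure class and each further digit refines it. Rare
codes make per-code statistics unreliable, so codes are aggregated bottom-up
over their prefix tree: a code with at least ``min_count`` patients keeps
its own group, under-threshold siblings merge into a residual group at the
parent prefix, and residuals still under threshold merge upward again until
the 2-digit top level, where residuals are retained regardless of size.
The resulting groups partition the observed codes and (except top-level
residuals) all meet the minimum count; their enumeration index is the
reduced discrete feature handed to the encoder.

The threshold itself is chosen by a grid search (candidates 50, 100, 150,
250, 500) scored by held-out univariate AUC of the encoded grouping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .encoding import apply_encoder, fit_encoder
from .synthetic import MISSING_NOMINAL

GLOBAL_OTHER = "__other__"


def normalize_code(code: str) -> str:
    """Strip the decimal point and validate digit content (length 2-4).

    The reserved missing marker passes through unchanged and is treated as a
    top-level class of its own.
    """
    c = str(code).replace(".", "").strip()
    if c == MISSING_NOMINAL:
        return c
    if not c.isdigit() or not 2 <= len(c) <= 4:
        raise ValueError(f"invalid procedure code {code!r}")
    return c


@dataclass
class CodeTree:
    """Prefix tree over observed codes with per-node patient counts.

    ``subtree[p]`` counts every patient whose (normalized) code has prefix
    ``p``; ``exact[p]`` counts patients coded exactly ``p`` (codes shorter
    than 4 digits act as leaves at their own depth).
    """

    subtree: dict[str, int] = field(default_factory=dict)
    exact: dict[str, int] = field(default_factory=dict)
    children: dict[str, set[str]] = field(default_factory=dict)

    @property
    def top_classes(self) -> list[str]:
        return sorted(p for p in self.subtree if len(p) == 2 or p == MISSING_NOMINAL)

    @property
    def n(self) -> int:
        return sum(self.subtree.get(c, 0) for c in self.top_classes)


def build_prefix_tree(codes: Iterable[str]) -> CodeTree:
    """Build the prefix tree; node set = all observed prefixes of length 2-4."""
    tree = CodeTree()
    for raw in codes:
        c = normalize_code(raw)
        tree.exact[c] = tree.exact.get(c, 0) + 1
        if c == MISSING_NOMINAL:
            tree.subtree[c] = tree.subtree.get(c, 0) + 1
            continue
        for d in range(2, len(c) + 1):
            p = c[:d]
            tree.subtree[p] = tree.subtree.get(p, 0) + 1
            if d > 2:
                tree.children.setdefault(c[: d - 1], set()).add(p)
    return tree


@dataclass
class CodeGrouping:
    """Fitted partition of observed codes into count-sufficient groups."""

    code_to_group: dict[str, str]
    group_members: dict[str, list[str]]
    group_counts: dict[str, int]
    enumeration: dict[str, int]
    min_count: int

    @property
    def n_groups(self) -> int:
        return len(self.group_members)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeGrouping":
        return cls(**json.loads(Path(path).read_text()))


def aggregate_codes(
    tree: CodeTree, min_count: int = 100, global_residual: bool = False
) -> CodeGrouping:
    """Bottom-up aggregation until every group reaches ``min_count`` patients.

    Siblings are processed in lexicographic order for determinism. Residual
    groups are labelled ``<prefix>~``. Top-level residuals are retained even
    when under threshold; with ``global_residual=True`` they are instead
    pooled into one global ``__other__`` group.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    code_to_group: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    counts: dict[str, int] = {}

    def make_group(label: str, codes_: list[str], count: int) -> None:
        members[label] = sorted(codes_)
        counts[label] = count
        for c in codes_:
            code_to_group[c] = label

    for c2 in tree.top_classes:
        res2_codes: list[str] = []
        res2_count = 0
        # patients coded exactly at the 2-digit level behave as a leaf here
        if tree.exact.get(c2, 0) >= min_count:
            make_group(c2, [c2], tree.exact[c2])
        elif tree.exact.get(c2, 0) > 0:
            res2_codes.append(c2)
            res2_count += tree.exact[c2]
        for c3 in sorted(tree.children.get(c2, ())):
            res3_codes: list[str] = []
            res3_count = 0
            if tree.exact.get(c3, 0) >= min_count:
                make_group(c3, [c3], tree.exact[c3])
            elif tree.exact.get(c3, 0) > 0:
                res3_codes.append(c3)
                res3_count += tree.exact[c3]
            for c4 in sorted(tree.children.get(c3, ())):
                if tree.exact.get(c4, 0) >= min_count:
                    make_group(c4, [c4], tree.exact[c4])
                elif tree.exact.get(c4, 0) > 0:
                    res3_codes.append(c4)
                    res3_count += tree.exact[c4]
            if res3_codes:
                if res3_count >= min_count:
                    make_group(f"{c3}~", res3_codes, res3_count)
                else:
                    res2_codes.extend(res3_codes)
                    res2_count += res3_count
        if res2_codes:
            make_group(f"{c2}~", res2_codes, res2_count)

    if global_residual:
        pooled = [
            (label, members[label], counts[label])
            for label in list(members)
            if label.endswith("~") and counts[label] < min_count
        ]
        if pooled:
            all_codes: list[str] = []
            total = 0
            for label, mem, cnt in pooled:
                del members[label], counts[label]
                all_codes.extend(mem)
                total += cnt
            make_group(GLOBAL_OTHER, all_codes, total)

    enumeration = {label: i for i, label in enumerate(sorted(members))}
    return CodeGrouping(
        code_to_group=code_to_group,
        group_members=members,
        group_counts=counts,
        enumeration=enumeration,
        min_count=min_count,
    )


def apply_grouping(grouping: CodeGrouping, codes: Iterable[str]) -> np.ndarray:
    """Map codes to group labels; unseen codes fall back along their prefixes.

    An unseen code routes to the deepest existing ancestor group (the
    residual or exact group at its 3- then 2-digit prefix); a code from an
    entirely unseen class maps to the global ``__other__`` label.
    """
    out = []
    for raw in codes:
        c = normalize_code(raw)
        g = grouping.code_to_group.get(c)
        if g is None and c != MISSING_NOMINAL:
            for cand in (c[:3] + "~", c[:3], c[:2] + "~", c[:2]):
                if cand in grouping.group_members:
                    g = cand
                    break
        if g is None:
            g = GLOBAL_OTHER
        out.append(g)
    return np.array(out, dtype=object)


def grid_search_min_count(
    codes: Sequence[str],
    outcome: np.ndarray,
    candidates: Sequence[int] = (50, 100, 150, 250, 500),
    seed: int = 0,
    train_fraction: float = 0.7,
) -> tuple[int, dict[int, float]]:
    """Choose the aggregation threshold by held-out univariate AUC.

    For each candidate: aggregate the training codes, log-ratio-encode the
    grouping, fit a single-covariate logistic model, and score AUC on the
    held-out fold. Ties favour the smaller candidate. Deterministic given
    ``seed``.
    """
    from .evaluation import auc, stratified_split

    if not len(candidates):
        raise ValueError("candidate set is empty")
    codes = np.asarray(codes, dtype=object)
    outcome = np.asarray(outcome)
    plan = stratified_split(outcome, train_fraction=train_fraction, seed=seed)
    tr, va = plan.train_idx, plan.val_idx
    scores: dict[int, float] = {}
    for mc in sorted(candidates):
        tree = build_prefix_tree(codes[tr])
        grouping = aggregate_codes(tree, min_count=mc)
        g_tr = apply_grouping(grouping, codes[tr])
        g_va = apply_grouping(grouping, codes[va])
        enc = fit_encoder(g_tr, outcome[tr], min_count=1, smoothing=0.5, seed=seed)
        x_tr = apply_encoder(enc, g_tr).reshape(-1, 1)
        x_va = apply_encoder(enc, g_va).reshape(-1, 1)
        lr = LogisticRegression(max_iter=1000).fit(x_tr, outcome[tr])
        scores[mc] = auc(lr.predict_proba(x_va)[:, 1], outcome[va])
    best = max(sorted(scores), key=lambda k: scores[k])  # ties -> smaller candidate
    return best, scores
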