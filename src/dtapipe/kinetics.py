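"""Temporal classification of candidate genes into response groups.

Each candidate gene has a sign profile s = (s1, s2, s3) over the three
post-treatment days, where st is +1/-1 if the gene survived background
subtraction at day t as up-/down-regulated and 0 otherwise.  Profiles
map deterministically onto four response groups:

* Group IV — constant response: changed at day 1 AND still changed in
  the same direction at day 3 (day-2 status unconstrained, so a missed
  middle call is tolerated).
* Group I — early (transient or reversing) response: changed at day 1
  and not Group IV.
* Group II — middle response: first change at day 2 (s1 = 0, s2 != 0).
* Group III — late response: first change at day 3 (s1 = s2 = 0,
  s3 != 0).

These four predicates cover and partition all 26 nonzero sign profiles.
Within a group, sub-clusters are by default the exact sign patterns
(deterministic, reproducible); an average-linkage hierarchical mode on
the log2 fold-change profiles is available when a fixed cluster count
per group is wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from string import ascii_uppercase
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .formatting import percentage
from .responsive import TIMEPOINTS, ResponsiveSet

GROUPS = ("I", "II", "III", "IV")
_GROUP_NUMBER = {"I": 1, "II": 2, "III": 3, "IV": 4}
_DIR_TO_SIGN = {"up": 1, "down": -1, "none": 0}
_SIGN_TO_CHAR = {1: "+", -1: "-", 0: "0"}


class ClassificationError(ValueError):
    """Raised for profiles that cannot belong to a candidate gene."""


def sign_profiles(responsive: ResponsiveSet,
                  candidates: Iterable[str]) -> pd.DataFrame:
    """One row per candidate: gene_id, s1..s3, lfc_1d..lfc_3d, pattern."""
    candidates = set(candidates)
    missing = candidates - responsive.genes
    if missing:
        raise ClassificationError(
            f"candidates not in the responsive union: {sorted(missing)[:5]}")
    table = responsive.union[responsive.union["gene_id"].isin(candidates)].copy()
    for t in TIMEPOINTS:
        table[f"s{t}"] = table[f"dir_{t}d"].map(_DIR_TO_SIGN)
    table["pattern"] = [
        "".join(_SIGN_TO_CHAR[s] for s in signs)
        for signs in zip(table["s1"], table["s2"], table["s3"])
    ]
    cols = ["gene_id", "s1", "s2", "s3",
            "lfc_1d", "lfc_2d", "lfc_3d", "pattern"]
    return table[cols].reset_index(drop=True)


def assign_group(profile) -> str:
    """Map one (s1, s2, s3) sign profile to its response group."""
    s1, s2, s3 = (int(s) for s in profile)
    for s in (s1, s2, s3):
        if s not in (-1, 0, 1):
            raise ClassificationError(f"signs must be in -1/0/+1, got {profile}")
    if s1 == s2 == s3 == 0:
        raise ClassificationError("all-zero profile cannot be a candidate")
    if s1 != 0 and s3 != 0 and np.sign(s1) == np.sign(s3):
        return "IV"
    if s1 != 0:
        return "I"
    if s2 != 0:
        return "II"
    return "III"


def classify_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Add a ``group`` column; returns gene_id, pattern, group."""
    groups = [
        assign_group(signs)
        for signs in zip(profiles["s1"], profiles["s2"], profiles["s3"])
    ]
    return pd.DataFrame({
        "gene_id": profiles["gene_id"],
        "pattern": profiles["pattern"],
        "group": groups,
    })


def _letters(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — enough labels for any cluster count."""
    labels = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = ascii_uppercase[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(label)
    return labels


def subcluster(assignments: pd.DataFrame, profiles: pd.DataFrame,
               mode: str = "sign",
               n_clusters: dict[str, int] | int | None = None) -> pd.Series:
    """Sub-cluster labels (e.g. '1A') within each response group.

    ``mode='sign'`` (default) partitions a group by exact sign pattern,
    labelling patterns in lexicographic order — fully deterministic.
    ``mode='hierarchical'`` cuts an average-linkage Euclidean dendrogram
    of the log2 fold-change profiles into ``n_clusters`` clusters per
    group (int, or a per-group dict); cluster labels are ordered by each
    cluster's first gene in input order.
    """
    merged = assignments.merge(profiles, on="gene_id", suffixes=("", "_p"))
    labels = pd.Series(index=merged.index, dtype=object)
    for group, block in merged.groupby("group", sort=False):
        prefix = str(_GROUP_NUMBER[group])
        if mode == "sign":
            patterns = sorted(block["pattern"].unique())
            letter = dict(zip(patterns, _letters(len(patterns))))
            labels.loc[block.index] = [
                prefix + letter[p] for p in block["pattern"]
            ]
        elif mode == "hierarchical":
            k = n_clusters.get(group) if isinstance(n_clusters, dict) \
                else n_clusters
            if k is None:
                raise ClassificationError(
                    "hierarchical mode needs n_clusters")
            if k > len(block):
                raise ClassificationError(
                    f"group {group}: requested {k} clusters for "
                    f"{len(block)} genes")
            coords = block[["lfc_1d", "lfc_2d", "lfc_3d"]].to_numpy()
            if len(block) == 1:
                cluster_ids = np.array([1])
            else:
                cluster_ids = fcluster(
                    linkage(coords, method="average", metric="euclidean"),
                    t=k, criterion="maxclust")
            # relabel clusters by order of first appearance (deterministic)
            order = {cid: i for i, cid in enumerate(
                pd.unique(pd.Series(cluster_ids)))}
            letter = _letters(len(order))
            labels.loc[block.index] = [
                prefix + letter[order[cid]] for cid in cluster_ids
            ]
        else:
            raise ClassificationError(f"unknown subcluster mode {mode!r}")
    return pd.Series(labels.to_numpy(), index=assignments.index,
                     name="subcluster")


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts, percentages, and the heatmap-ready fold-change matrix."""

    total: int
    group_counts: dict[str, int]
    subcluster_counts: dict[str, int]
    up_by_day: dict[int, int]
    down_by_day: dict[int, int]
    group_pct: dict[str, float]
    day1_responder_pct: float
    up_pct: float
    down_pct: float
    heatmap: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "group_counts": self.group_counts,
            "subcluster_counts": self.subcluster_counts,
            "up_by_day": {str(k): v for k, v in self.up_by_day.items()},
            "down_by_day": {str(k): v for k, v in self.down_by_day.items()},
            "group_pct": self.group_pct,
            "day1_responder_pct": self.day1_responder_pct,
            "up_pct": self.up_pct,
            "down_pct": self.down_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize_classification(assignments: pd.DataFrame,
                             profiles: pd.DataFrame) -> ClassificationSummary:
    """Accounting over an assignment table (gene_id, group, subcluster).

    ``up_by_day[t]``/``down_by_day[t]`` count genes with st = +1/-1; the
    day-1 responder percentage is the share of candidates already
    changed at day 1 (groups I and IV).  A gene's overall up/down label
    is the sign of its first nonzero timepoint.  All percentages are
    100 * part / total rounded half-up to two decimals.
    """
    if len(assignments) == 0:
        raise ClassificationError("empty assignment table")
    merged = assignments.merge(profiles, on="gene_id", suffixes=("", "_p"))
    total = len(merged)
    group_counts = {g: int((merged["group"] == g).sum()) for g in GROUPS}
    if "subcluster" in merged.columns:
        subcluster_counts = {
            str(k): int(v)
            for k, v in merged["subcluster"].value_counts().sort_index().items()
        }
    else:
        subcluster_counts = {}
    up_by_day = {t: int((merged[f"s{t}"] == 1).sum()) for t in TIMEPOINTS}
    down_by_day = {t: int((merged[f"s{t}"] == -1).sum()) for t in TIMEPOINTS}

    signs = merged[["s1", "s2", "s3"]].to_numpy()
    first_nonzero = np.array([
        row[np.nonzero(row)[0][0]] for row in signs
    ])
    n_up = int((first_nonzero > 0).sum())
    n_down = int((first_nonzero < 0).sum())

    sort_cols = ["group"]
    if "subcluster" in merged.columns:
        sort_cols.append("subcluster")
    ordered = merged.sort_values(
        sort_cols + ["gene_id"],
        key=lambda col: col.map(_GROUP_NUMBER) if col.name == "group" else col,
        kind="stable")
    heat_cols = ["gene_id", "group"] + \
        (["subcluster"] if "subcluster" in merged.columns else []) + \
        ["lfc_1d", "lfc_2d", "lfc_3d"]
    heatmap = ordered[heat_cols].reset_index(drop=True)

    return ClassificationSummary(
        total=total,
        group_counts=group_counts,
        subcluster_counts=subcluster_counts,
        up_by_day=up_by_day,
        down_by_day=down_by_day,
        group_pct={g: percentage(c, total) for g, c in group_counts.items()},
        day1_responder_pct=percentage(
            group_counts["I"] + group_counts["IV"], total),
        up_pct=percentage(n_up, total),
        down_pct=percentage(n_down, total),
        heatmap=heatmap,
    )
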