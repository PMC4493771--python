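"""Control-background elimination and the ethephon-responsive union.

Untreated control pedicels also change over the three-day time course
(development, wounding, weather), so a treatment-vs-control call at day
t is only attributed to ethephon if the same gene is NOT already a
control-drift call (CK0 vs CKt).  The surviving per-timepoint sets are
denoted ETHt/CKt; their union over t = 1..3 is the ethephon-responsive
gene set, each member carrying a direction vector (up/down/none per
timepoint) and its per-timepoint log2 fold changes for downstream
classification and heatmap export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .detest import CONTROL_PAIRS, TREATMENT_PAIRS

TIMEPOINTS = (1, 2, 3)


class ResponsiveError(ValueError):
    """Raised for mismatched gene universes or missing comparisons."""


def _called(degs: pd.DataFrame) -> pd.DataFrame:
    return degs[degs["direction"] != "none"]


def subtract_background(treatment_degs: pd.DataFrame,
                        control_degs: pd.DataFrame,
                        direction_aware: bool = False) -> pd.DataFrame:
    """Treatment calls whose gene does not appear among control calls.

    By default exclusion is by gene id only — a gene drifting *down* in
    the untreated control is still removed from the *up* treatment calls,
    because the drift makes its treatment attribution unreliable either
    way.  ``direction_aware=True`` removes only same-direction control
    calls.  Directions in the result come from the treatment comparison.
    """
    t_universe = set(treatment_degs["gene_id"])
    c_universe = set(control_degs["gene_id"])
    if t_universe != c_universe:
        raise ResponsiveError("treatment and control gene universes differ")
    treat = _called(treatment_degs)
    ctrl = _called(control_degs)
    if direction_aware:
        ctrl_keys = set(zip(ctrl["gene_id"], ctrl["direction"]))
        keep = [
            (g, d) not in ctrl_keys
            for g, d in zip(treat["gene_id"], treat["direction"])
        ]
    else:
        ctrl_ids = set(ctrl["gene_id"])
        keep = [g not in ctrl_ids for g in treat["gene_id"]]
    return treat.loc[keep, ["gene_id", "direction", "log2fc"]].reset_index(drop=True)


@dataclass(frozen=True)
class ResponsiveSet:
    """Per-timepoint background-subtracted calls and their union.

    ``per_timepoint[t]`` holds the ETHt/CKt table (gene_id, direction,
    log2fc); ``union`` has one row per responsive gene with columns
    dir_1d/dir_2d/dir_3d (up/down/none) and lfc_1d/lfc_2d/lfc_3d (the
    treatment-comparison log2 fold changes at every timepoint, called or
    not, for clustering and heatmaps).
    """

    per_timepoint: dict[int, pd.DataFrame]
    union: pd.DataFrame

    @property
    def genes(self) -> set[str]:
        return set(self.union["gene_id"])

    def directions(self, gene_id: str) -> tuple[str, str, str]:
        row = self.union.loc[self.union["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return (r["dir_1d"], r["dir_2d"], r["dir_3d"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for t, table in self.per_timepoint.items():
            table.to_csv(outdir / f"responsive_eth{t}_ck{t}.tsv",
                         sep="\t", index=False)
        self.union.to_csv(outdir / "responsive_union.tsv", sep="\t", index=False)


def build_responsive(deg_tables: Mapping[tuple[str, str], pd.DataFrame],
                     direction_aware: bool = False) -> ResponsiveSet:
    """Build ETHt/CKt for t = 1..3 and their union from the six pair tables."""
    for pair in CONTROL_PAIRS + TREATMENT_PAIRS:
        if pair not in deg_tables:
            raise ResponsiveError(f"missing comparison {pair}")
    per_timepoint: dict[int, pd.DataFrame] = {}
    for t, (ctrl_pair, treat_pair) in enumerate(
            zip(CONTROL_PAIRS, TREATMENT_PAIRS), start=1):
        per_timepoint[t] = subtract_background(
            deg_tables[treat_pair], deg_tables[ctrl_pair],
            direction_aware=direction_aware)

    union_ids = sorted(
        set().union(*(set(tab["gene_id"]) for tab in per_timepoint.values())))
    rows = []
    dir_maps = {
        t: dict(zip(tab["gene_id"], tab["direction"]))
        for t, tab in per_timepoint.items()
    }
    lfc_maps = {
        t: dict(zip(deg_tables[pair]["gene_id"], deg_tables[pair]["log2fc"]))
        for t, pair in zip(TIMEPOINTS, TREATMENT_PAIRS)
    }
    for gene in union_ids:
        row = {"gene_id": gene}
        for t in TIMEPOINTS:
            row[f"dir_{t}d"] = dir_maps[t].get(gene, "none")
            row[f"lfc_{t}d"] = lfc_maps[t].get(gene, 0.0)
        rows.append(row)
    columns = ["gene_id"] + [f"dir_{t}d" for t in TIMEPOINTS] + \
        [f"lfc_{t}d" for t in TIMEPOINTS]
    union = pd.DataFrame(rows, columns=columns)
    return ResponsiveSet(per_timepoint=per_timepoint, union=union)
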