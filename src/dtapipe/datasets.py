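"""Published summary numbers of the litchi ethephon-abscission experiment.

The original experiment (FAZ-enriched pedicel, seven pooled tag
libraries CK0..CK3 / ETH1..ETH3) deposited no raw reads, so its
genome-scale gene lists cannot be recomputed; what *is* reproducible is
the accounting printed with it — the sequencing/mapping table, the
response-group and sub-cluster sizes, and the functional-category
breakdowns.  This module holds those printed integers and builds
fixture tables from them so the summary/reporting operations can be
checked against the published arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import ACCOUNTING_COLUMNS

#: Sequencing and mapping statistics: total, mapped, unique-match reads.
LIBRARY_ACCOUNTING: dict[str, tuple[int, int, int]] = {
    "CK0": (12_009_135, 10_461_248, 4_491_205),
    "CK1": (11_530_205, 10_022_661, 4_400_232),
    "CK2": (10_568_766, 9_161_789, 4_003_146),
    "CK3": (10_862_567, 9_472_399, 4_147_267),
    "ETH1": (12_477_700, 10_921_142, 4_756_944),
    "ETH2": (11_905_084, 10_401_413, 4_516_857),
    "ETH3": (12_284_279, 10_628_560, 4_693_781),
}

#: Candidate genes per temporal response group.
GROUP_SIZES: dict[str, int] = {"I": 1867, "II": 148, "III": 258, "IV": 457}

#: Sub-cluster sizes within Group I (clusters 1A..1F).
GROUP_I_CLUSTER_SIZES: tuple[int, ...] = (172, 261, 55, 776, 434, 169)

#: Candidate genes up-/down-regulated at day 1, and at day 2-or-3.
DAY1_UP, DAY1_DOWN = 723, 1601
LATE_UP, LATE_DOWN = 299, 107

#: Overall up/down split of the 2730 candidates.
CANDIDATES_UP, CANDIDATES_DOWN = 1022, 1708

#: Set sizes along the screen.
RESPONSIVE_TOTAL = 6167
GO_ANNOTATED = 3249          # responsive genes with a GO category
GO_BRANCH, KEGG_BRANCH = 2471, 2344
CANDIDATE_TOTAL = 2730

#: Functional-category counts among the candidates.
HORMONE_GENES_BY_GROUP = (124, 16, 17, 38)      # groups I..IV
TF_UP_DOWN = (51, 76)                            # beyond hormone-related TFs
CELL_WALL_BY_ROLE = (56, 104, 21, 27)            # synthesis/degradation/loosening/modification
ROS_UP_DOWN = (39, 49)


def accounting_frame() -> pd.DataFrame:
    """LIBRARY_ACCOUNTING as the DataFrame ``library_stats`` consumes."""
    frame = pd.DataFrame.from_dict(
        LIBRARY_ACCOUNTING, orient="index", columns=list(ACCOUNTING_COLUMNS))
    frame.index.name = "library"
    return frame


def reported_group_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(assignments, profiles) tables realizing the published accounting.

    Builds one gene row per published candidate: the four groups at
    their published sizes, with day-1 up/down split 723/1601 across the
    early groups (I and IV) and Group I sub-clusters at the published
    1A..1F sizes.  Fold-change columns carry the sign pattern scaled to
    the four-fold gate (|log2fc| = 2), enough for the accounting and
    heatmap-ordering checks this fixture exists for.
    """
    rows = []
    idx = 0

    def add(n: int, s1: int, s2: int, s3: int, subcluster: str | None = None):
        nonlocal idx
        for _ in range(n):
            rows.append({
                "gene_id": f"PUB{idx:05d}", "s1": s1, "s2": s2, "s3": s3,
                "subcluster": subcluster,
            })
            idx += 1

    # Group I at the published sub-cluster sizes; 723 of the 2324
    # day-1-changed genes (groups I and IV) are up-regulated, and the
    # published panels place all of those within Group I.
    remaining_up = DAY1_UP
    for letter, size in zip("ABCDEF", GROUP_I_CLUSTER_SIZES):
        n_up = min(size, remaining_up)
        remaining_up -= n_up
        add(n_up, 1, 0, 0, f"1{letter}")
        add(size - n_up, -1, 0, 0, f"1{letter}")
    add(GROUP_SIZES["II"], 0, 1, 0, "2A")
    add(GROUP_SIZES["III"], 0, 0, 1, "3A")
    add(GROUP_SIZES["IV"], -1, 0, -1, "4A")

    table = pd.DataFrame(rows)
    sign_char = {1: "+", -1: "-", 0: "0"}
    table["pattern"] = [
        "".join(sign_char[s] for s in signs)
        for signs in zip(table["s1"], table["s2"], table["s3"])
    ]
    for t in (1, 2, 3):
        table[f"lfc_{t}d"] = 2.0 * table[f"s{t}"]

    profiles = table[["gene_id", "s1", "s2", "s3",
                      "lfc_1d", "lfc_2d", "lfc_3d", "pattern"]].copy()
    from .kinetics import classify_profiles  # deferred: avoids import cycle
    assignments = classify_profiles(profiles)
    assignments["subcluster"] = table["subcluster"].to_numpy()
    return assignments, profiles


def functional_category_totals() -> dict[str, int]:
    """Summed functional-category counts among the candidate genes."""
    return {
        "hormone": int(np.sum(HORMONE_GENES_BY_GROUP)),
        "transcription_factor": int(np.sum(TF_UP_DOWN)),
        "cell_wall": int(np.sum(CELL_WALL_BY_ROLE)),
        "ros": int(np.sum(ROS_UP_DOWN)),
    }
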