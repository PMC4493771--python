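"""Relative quantification by the comparative-Ct (2^-ddCt) method.

Target Ct values are normalized against the mean of two reference genes
(EF-1a and GAPDH in the litchi assays this emulates), then against the
pre-treatment 0 d calibrator sample, giving relative expression
RE = 2^(-ddCt) with RE(0 d) = 1 exactly.  ``concordance`` scores these
qPCR profiles against the tag-count RPKM profiles of the same genes —
the cross-platform validation step of the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .quantify import ExpressionMatrix

CT_COLUMNS = ("gene_id", "sample", "replicate", "ct", "is_reference")
DEFAULT_CALIBRATOR = "0d"
#: qPCR sample label -> tag-library of the same tissue/timepoint.
DEFAULT_SAMPLE_MAP: dict[str, str] = {
    "0d": "CK0", "1d": "ETH1", "2d": "ETH2", "3d": "ETH3",
}
#: Minimal linear fold for a change to count as a direction (not noise).
DEFAULT_MIN_FOLD = 1.5
_RPKM_FLOOR = 1e-6  # keeps unexpressed-gene ratios finite


class QpcrError(ValueError):
    """Raised for Ct tables missing references, calibrator, or genes."""


def load_ct_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise QpcrError(f"Ct table missing columns: {missing}")
    if (frame["ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")
    return frame


def delta_delta_ct(records: pd.DataFrame,
                   calibrator: str = DEFAULT_CALIBRATOR) -> pd.DataFrame:
    """Relative expression per (target gene, sample) from a Ct table.

    dCt(sample) = mean replicate Ct(target) - mean of the per-reference
    mean Cts; ddCt = dCt(sample) - dCt(calibrator); RE = 2^-ddCt.
    Requires every reference gene in every sample and the calibrator
    sample for every target.
    """
    refs = records[records["is_reference"].astype(bool)]
    targets = records[~records["is_reference"].astype(bool)]
    if refs.empty:
        raise QpcrError("no reference genes in the Ct table")
    samples = sorted(records["sample"].unique())
    ref_genes = sorted(refs["gene_id"].unique())

    # mean Ct per (reference gene, sample), then mean across references
    ref_means = refs.groupby(["sample", "gene_id"])["ct"].mean()
    ref_ct = {}
    for sample in samples:
        per_gene = [
            ref_means.get((sample, g)) for g in ref_genes
        ]
        if any(v is None or pd.isna(v) for v in per_gene):
            raise QpcrError(f"sample {sample!r} is missing a reference gene")
        ref_ct[sample] = float(np.mean(per_gene))

    rows = []
    for gene, block in targets.groupby("gene_id"):
        mean_ct = block.groupby("sample")["ct"].mean()
        if calibrator not in mean_ct.index:
            raise QpcrError(
                f"gene {gene!r} has no calibrator sample {calibrator!r}")
        dct = {s: mean_ct[s] - ref_ct[s] for s in mean_ct.index}
        for sample in mean_ct.index:
            ddct = dct[sample] - dct[calibrator]
            rows.append({
                "gene_id": gene,
                "sample": sample,
                "relative_expression": float(2.0 ** (-ddct)),
            })
    return pd.DataFrame(rows, columns=["gene_id", "sample",
                                       "relative_expression"])


def _fold_direction(ratio: float, min_fold: float) -> int:
    if ratio >= min_fold:
        return 1
    if ratio <= 1.0 / min_fold:
        return -1
    return 0


def concordance(qpcr: pd.DataFrame, dta: ExpressionMatrix,
                genes: Iterable[str] | None = None,
                min_fold: float = DEFAULT_MIN_FOLD,
                method: str = "day1",
                sample_map: Mapping[str, str] = DEFAULT_SAMPLE_MAP,
                calibrator: str = DEFAULT_CALIBRATOR,
                ) -> tuple[pd.DataFrame, dict]:
    """Score qPCR relative-expression profiles against RPKM profiles.

    ``method='day1'`` (default): a gene is concordant iff the direction
    of its day-1 change versus the 0 d calibrator (up at fold >=
    ``min_fold``, down at <= 1/``min_fold``, else no change) agrees
    between the two platforms.  ``method='spearman'``: concordant iff
    the Spearman correlation of the two profiles over the mapped samples
    is positive.  Returns the per-gene table and a summary dict with
    concordant/total counts.
    """
    if genes is None:
        genes = sorted(qpcr["gene_id"].unique())
    else:
        genes = list(genes)
    re_lookup = qpcr.set_index(["gene_id", "sample"])["relative_expression"]
    day1_sample = next(s for s in sample_map if s != calibrator)

    rows = []
    for gene in genes:
        if gene not in dta.rpkm.index:
            raise QpcrError(f"gene {gene!r} absent from the expression matrix")
        try:
            re_profile = [re_lookup[(gene, s)] for s in sample_map]
        except KeyError as exc:
            raise QpcrError(f"gene {gene!r} missing qPCR sample {exc}") from exc
        rpkm_profile = [
            dta.rpkm.at[gene, lib] + _RPKM_FLOOR for lib in sample_map.values()
        ]
        if method == "day1":
            q_dir = _fold_direction(
                re_lookup[(gene, day1_sample)], min_fold)
            d_ratio = rpkm_profile[list(sample_map).index(day1_sample)] / \
                rpkm_profile[list(sample_map).index(calibrator)]
            d_dir = _fold_direction(d_ratio, min_fold)
            concordant = q_dir == d_dir
            rows.append({"gene_id": gene, "qpcr_direction": q_dir,
                         "dta_direction": d_dir, "concordant": concordant})
        elif method == "spearman":
            rho = _scipy_stats.spearmanr(re_profile, rpkm_profile).statistic
            rows.append({"gene_id": gene, "spearman_rho": float(rho),
                         "concordant": bool(rho > 0)})
        else:
            raise QpcrError(f"unknown concordance method {method!r}")
    table = pd.DataFrame(rows)
    summary = {
        "method": method,
        "concordant": int(table["concordant"].sum()),
        "total": len(table),
    }
    return table, summary


def write_concordance(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
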