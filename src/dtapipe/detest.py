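"""Differential expression between two unreplicated tag libraries.

The design has no biological replicates per library (replicates were
pooled before sequencing), so significance comes from the exact
conditional test of Audic & Claverie for two count libraries: given the
count ``x`` observed in a library of size ``N1``, the count ``Y`` in a
second library of size ``N2`` follows, under the null of equal relative
abundance and a flat prior,

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1))

which is exactly a negative binomial with ``x + 1`` successes and
success probability ``N1 / (N1 + N2)``.  The two-sided p-value doubles
the smaller tail and caps at 1.  A gene is called differentially
expressed only if it passes the dual gate used for this design:
FDR <= 0.001 (Benjamini-Hochberg) and a four-fold change on
pseudo-counted, library-size-normalized counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

#: Control drift pairs: same untreated tissue at 0 d vs later days.
CONTROL_PAIRS: tuple[tuple[str, str], ...] = (
    ("CK0", "CK1"), ("CK0", "CK2"), ("CK0", "CK3"),
)
#: Treatment-vs-control pairs at matched timepoints.
TREATMENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("CK1", "ETH1"), ("CK2", "ETH2"), ("CK3", "ETH3"),
)
#: The six fixed comparisons of the design, (reference, test) order.
STANDARD_PAIRS: tuple[tuple[str, str], ...] = CONTROL_PAIRS + TREATMENT_PAIRS

#: Dual-gate defaults: FDR cutoff and linear fold-change cutoff.
DEFAULT_FDR = 1e-3
DEFAULT_FOLD_CHANGE = 4.0
PSEUDOCOUNT = 1.0

DEG_COLUMNS = ("gene_id", "x", "y", "log2fc", "pvalue", "fdr", "direction")


class DomainError(ValueError):
    """Raised for out-of-domain test inputs (negative counts, empty sets...)."""


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value(s) for counts ``x`` vs ``y``.

    Parameters are broadcastable arrays; ``n1``/``n2`` are the library
    sizes of the ``x``/``y`` libraries.  Computed through the negative
    binomial identity above (log-space internally), so counts up to 1e6
    neither overflow nor underflow.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("counts must be non-negative")
    if np.any(x != np.floor(x)) or np.any(y != np.floor(y)):
        raise DomainError("counts must be integers")
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise DomainError("library sizes must be >= 1")
    p_success = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p_success)   # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)  # P(Y >= y | x)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if p.ndim else float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(counts: CountMatrix, pair: tuple[str, str],
              fdr_threshold: float = DEFAULT_FDR,
              fc_threshold: float = DEFAULT_FOLD_CHANGE) -> pd.DataFrame:
    """Test every gene of ``counts`` between one (reference, test) pair.

    Returns one row per gene with columns gene_id, x, y, log2fc, pvalue,
    fdr and direction in {'up', 'down', 'none'}.  log2fc is
    log2(((y + 1) / N2) / ((x + 1) / N1)): the pseudo-count keeps on/off
    genes finite.  Genes exactly at either threshold are called (the
    gates are inclusive).
    """
    reference, test = pair
    if reference == test:
        raise DomainError("pair labels must be distinct")
    counts.require_libraries(pair)
    if counts.n_genes == 0:
        raise DomainError("empty gene universe")
    if not (0 < fdr_threshold <= 1):
        raise DomainError("fdr_threshold must be in (0, 1]")
    if fc_threshold < 1:
        raise DomainError("fc_threshold must be >= 1")

    x = counts.counts[reference].to_numpy()
    y = counts.counts[test].to_numpy()
    totals = counts.totals()
    n1 = float(totals[reference])
    n2 = float(totals[test])
    pvals = ac_pvalue(x, y, n1, n2)
    fdr = bh_fdr(pvals)
    log2fc = np.log2(((y + PSEUDOCOUNT) / n2) / ((x + PSEUDOCOUNT) / n1))
    called = (fdr <= fdr_threshold) & (np.abs(log2fc) >= np.log2(fc_threshold))
    direction = np.where(called, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame({
        "gene_id": counts.gene_ids,
        "x": x,
        "y": y,
        "log2fc": log2fc,
        "pvalue": pvals,
        "fdr": fdr,
        "direction": direction,
    })


def call_all_pairs(counts: CountMatrix,
                   pairs: tuple[tuple[str, str], ...] = STANDARD_PAIRS,
                   fdr_threshold: float = DEFAULT_FDR,
                   fc_threshold: float = DEFAULT_FOLD_CHANGE,
                   ) -> dict[tuple[str, str], pd.DataFrame]:
    """``call_degs`` over every pair of the design."""
    return {
        pair: call_degs(counts, pair, fdr_threshold, fc_threshold)
        for pair in pairs
    }
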