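"""Term enrichment of the responsive set and the candidate-gene screen.

Responsive genes are screened through two flat term vocabularies (a
GO-like functional one and a KEGG-like pathway one) with the upper-tail
hypergeometric test: for a term containing K of the N background genes,
the probability of seeing >= k of them among the n responsive genes by
chance.  Terms are significant at adjusted value <= 0.05 in either
vocabulary; candidate genes are the responsive genes belonging to at
least one significant term of either vocabulary, deduplicated.

No ancestor propagation is done on the GO-like vocabulary: terms are
treated as flat gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .detest import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class EnrichmentError(ValueError):
    """Raised for empty study/background sets or malformed annotations."""


@dataclass(frozen=True)
class AnnotationMap:
    """A flat term -> gene-set vocabulary (GO-like or KEGG-like)."""

    vocabulary: str
    terms: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empties = [t for t, genes in self.terms.items() if not genes]
        if empties:
            raise EnrichmentError(f"empty terms not allowed: {empties[:5]}")

    @property
    def genes(self) -> frozenset:
        return frozenset().union(*self.terms.values()) if self.terms else frozenset()

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationMap":
        """Drop genes outside ``universe`` (and terms emptied by that)."""
        universe = frozenset(universe)
        dropped = self.genes - universe
        if dropped:
            logger.warning(
                "%s: dropping %d annotated genes outside the background universe",
                self.vocabulary, len(dropped))
        kept = {
            term: genes & universe
            for term, genes in self.terms.items()
            if genes & universe
        }
        return AnnotationMap(vocabulary=self.vocabulary, terms=kept,
                             names=self.names)

    # -- IO (two-column TSV with a vocabulary-naming header) ---------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        path = Path(path)
        vocabulary = "GO-like"
        with open(path) as handle:
            first = handle.readline().strip()
            if first.startswith("#"):
                vocabulary = first.lstrip("#").split("=")[-1].strip()
                frame = pd.read_csv(handle, sep="\t")
            else:
                handle.seek(0)
                frame = pd.read_csv(handle, sep="\t")
        if not {"term_id", "gene_id"} <= set(frame.columns):
            raise EnrichmentError(
                f"{path}: annotation TSV needs term_id and gene_id columns")
        terms = {
            term: frozenset(group["gene_id"])
            for term, group in frame.groupby("term_id")
        }
        return cls(vocabulary=vocabulary, terms=terms)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# vocabulary={self.vocabulary}\n")
            handle.write("term_id\tgene_id\n")
            for term in sorted(self.terms):
                for gene in sorted(self.terms[term]):
                    handle.write(f"{term}\t{gene}\n")


def storey_qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    pi0 = min(1, #{p > lambda} / (m * (1 - lambda))); q = pi0 * BH(p).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    pi0 = min(1.0, float(np.mean(p > lambda_)) / (1.0 - lambda_))
    pi0 = max(pi0, 1.0 / p.size)  # guard against pi0 == 0 on tiny inputs
    return np.minimum(1.0, pi0 * bh_fdr(p))


def hypergeom_enrich(study: Iterable[str], background: Iterable[str],
                     annot: AnnotationMap, alpha: float = DEFAULT_ALPHA,
                     method: str = "bh") -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    Returns one row per term sorted by p-value, with k (study genes in
    term), K (background genes in term), n (study size), N (background
    size), pvalue, adjusted (BH by default, Storey q with
    ``method='storey'``) and a ``significant`` flag at
    ``adjusted <= alpha``.
    """
    study = frozenset(study)
    background = frozenset(background)
    if not study or not background:
        raise EnrichmentError("study and background sets must be non-empty")
    if not study <= background:
        raise EnrichmentError("study set must be a subset of the background")
    annot = annot.restricted_to(background)
    if not annot.terms:
        raise EnrichmentError(f"{annot.vocabulary}: no terms in the background")

    n_bg = len(background)
    n_study = len(study)
    term_ids = sorted(annot.terms)
    k = np.array([len(annot.terms[t] & study) for t in term_ids])
    big_k = np.array([len(annot.terms[t]) for t in term_ids])
    # P(X >= k) with X ~ Hypergeom(N, K, n)
    pvals = stats.hypergeom.sf(k - 1, n_bg, big_k, n_study)
    adjusted = storey_qvalues(pvals) if method == "storey" else bh_fdr(pvals)
    result = pd.DataFrame({
        "term_id": term_ids,
        "k": k,
        "K": big_k,
        "n": n_study,
        "N": n_bg,
        "pvalue": pvals,
        "adjusted": adjusted,
        "significant": adjusted <= alpha,
    })
    return result.sort_values("pvalue", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class CandidateSet:
    """The candidate-gene screen result: two branches and their union."""

    go_branch: frozenset
    kegg_branch: frozenset

    @property
    def candidates(self) -> frozenset:
        return self.go_branch | self.kegg_branch

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "go_branch": len(self.go_branch),
            "kegg_branch": len(self.kegg_branch),
            "intersection": len(self.go_branch & self.kegg_branch),
            "union": len(self.candidates),
        }


def select_candidates(go_results: pd.DataFrame, kegg_results: pd.DataFrame,
                      annot_go: AnnotationMap, annot_kegg: AnnotationMap,
                      responsive_genes: Iterable[str]) -> CandidateSet:
    """Responsive genes in >= 1 significant term of either vocabulary."""
    responsive_genes = frozenset(responsive_genes)

    def branch(results: pd.DataFrame, annot: AnnotationMap) -> frozenset:
        significant = results.loc[results["significant"], "term_id"]
        members: set[str] = set()
        for term in significant:
            members |= annot.terms.get(term, frozenset())
        return frozenset(members & responsive_genes)

    return CandidateSet(go_branch=branch(go_results, annot_go),
                        kegg_branch=branch(kegg_results, annot_kegg))
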