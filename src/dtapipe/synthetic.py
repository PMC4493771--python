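"""Synthetic seven-library tag-count experiments with known planted truth.

The generator emulates the abscission time-course design: seven
unreplicated pooled-replicate libraries (CK0..CK3 untreated, ETH1..ETH3
ethephon-treated at days 1-3), counts drawn per gene and library from a
negative binomial around a log-uniform baseline.  A configurable
fraction of genes carries a planted temporal pattern — a string over
{+, -, 0} giving the sign of the ethephon effect at each of the three
days (e.g. ``"+00"`` = up at day 1 only, ``"+++"`` = persistently up).
Annotation vocabularies with planted term enrichment and qPCR Ct tables
with planted shifts complete the inputs, so differential testing,
background subtraction, enrichment, temporal classification and the
2^-ddCt validation can all be scored against ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import DEFAULT_LIBRARIES, CountMatrix

PATTERN_ALPHABET = "+-0"
NULL_PATTERN = "null"
_CHAR_TO_SIGN = {"+": 1, "-": -1, "0": 0}

# seed-derivation section tags (master seed + section -> independent stream)
_SECTION_BASELINE = 1
_SECTION_PATTERNS = 2
_SECTION_DRIFT = 3
_SECTION_COUNTS = 4
_SECTION_ANNOTATION = 5
_SECTION_CT = 6


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class AnnotationConfig:
    """Parameters of one synthetic term vocabulary.

    ``enrichment_strength`` is the probability that a member of an
    enriched term is drawn from the planted (non-null) genes rather than
    uniformly; 1.0 fills enriched terms entirely with planted genes.
    """

    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    n_enriched_terms: int = 5
    enrichment_strength: float = 0.9

    def validate(self, n_genes: int) -> None:
        lo, hi = self.term_size_range
        if self.n_terms < 0:
            raise SimConfigError("n_terms must be >= 0")
        if not (1 <= lo <= hi):
            raise SimConfigError("term_size_range must be a non-empty range >= 1")
        if hi > n_genes:
            raise SimConfigError("term sizes cannot exceed the gene universe")
        if not (0 <= self.n_enriched_terms <= self.n_terms):
            raise SimConfigError("n_enriched_terms must be in [0, n_terms]")
        if not (0.0 <= self.enrichment_strength <= 1.0):
            raise SimConfigError("enrichment_strength must be in [0, 1]")


def _default_fractions() -> dict[str, float]:
    # All four temporal response classes are represented: early-only,
    # middle-only, late-only, and persistent patterns.
    return {
        "+00": 0.03, "-00": 0.03,
        "0+0": 0.015, "0-0": 0.015,
        "00+": 0.015, "00-": 0.015,
        "+++": 0.02, "---": 0.02,
    }


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic experiment.

    Defaults give a desk-scale experiment: 1000 genes at a target depth
    of one million assigned reads per library, baseline abundances
    log-uniform over three orders of magnitude (so the exact test is
    stressed at low counts), mild negative-binomial overdispersion, and
    planted 8-fold effects (comfortably above the pipeline's four-fold
    gate) on 16% of genes.
    """

    n_genes: int = 1000
    library_depth: int = 1_000_000
    gene_length_range: tuple[int, int] = (200, 3000)
    dispersion: float = 0.02
    planted_fractions: Mapping[str, float] = field(
        default_factory=_default_fractions)
    effect_log2fc: float = 3.0
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    abundance_range: tuple[float, float] = (1.0, 1000.0)
    control_drift_fraction: float = 0.0
    control_drift_log2fc: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if self.library_depth <= 0:
            raise SimConfigError("library_depth must be positive")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise SimConfigError("gene_length_range must be non-empty and >= 1")
        alo, ahi = self.abundance_range
        if not (0 < alo <= ahi):
            raise SimConfigError("abundance_range must be non-empty and > 0")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.effect_log2fc < 2:
            raise SimConfigError(
                "effect_log2fc must be >= 2 (>= four-fold planted effects)")
        total = 0.0
        for pattern, frac in self.planted_fractions.items():
            if (len(pattern) != 3
                    or any(c not in PATTERN_ALPHABET for c in pattern)
                    or pattern == "000"):
                raise SimConfigError(f"invalid pattern label {pattern!r}")
            if frac < 0:
                raise SimConfigError("planted fractions must be >= 0")
            total += frac
        if total > 1.0 + 1e-12:
            raise SimConfigError("planted fractions must sum to <= 1")
        if not (0.0 <= self.control_drift_fraction <= 1.0):
            raise SimConfigError("control_drift_fraction must be in [0, 1]")
        self.annotation.validate(self.n_genes)


def pattern_signs(pattern: str) -> tuple[int, int, int]:
    """Sign triple of a pattern label ('+0-' -> (1, 0, -1))."""
    if pattern == NULL_PATTERN:
        return (0, 0, 0)
    return tuple(_CHAR_TO_SIGN[c] for c in pattern)  # type: ignore[return-value]


@dataclass
class SyntheticTruth:
    """Planted per-gene temporal effects and per-term enrichment flags."""

    genes: pd.DataFrame
    enriched_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def non_null(self) -> pd.DataFrame:
        return self.genes[self.genes["pattern"] != NULL_PATTERN]

    @property
    def null_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["pattern"] == NULL_PATTERN]

    @property
    def drift_genes(self) -> pd.DataFrame:
        drift = self.genes[["drift_1d", "drift_2d", "drift_3d"]].abs().sum(axis=1)
        return self.genes[drift > 0]

    def pattern_of(self, gene_id: str) -> str:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return row.iloc[0]["pattern"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "enriched_terms": {k: list(v) for k, v in self.enriched_terms.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            enriched_terms={
                k: tuple(v) for k, v in payload["enriched_terms"].items()
            },
        )


def _rng(seed: int, *sections: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *sections]))


def _sample_counts(rng: np.random.Generator, mean: np.ndarray,
                   dispersion: float) -> np.ndarray:
    """Negative-binomial counts (mean mu, variance mu + d*mu^2); d=0 -> Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def generate_experiment(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one seven-library experiment and its planted truth.

    Control libraries share the baseline expectation per gene (plus any
    configured control drift at days 1-3, applied to CKt *and* ETHt so
    it cancels in the treatment comparison); ETH libraries additionally
    carry the planted per-timepoint effects ``2^(sign * effect_log2fc)``.
    Identical seeds reproduce identical matrices bit-for-bit.
    """
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    rng_base = _rng(config.seed, _SECTION_BASELINE)
    alo, ahi = config.abundance_range
    weights = np.exp(rng_base.uniform(np.log(alo), np.log(ahi), size=n))
    baseline = config.library_depth * weights / weights.sum()
    llo, lhi = config.gene_length_range
    lengths = rng_base.integers(llo, lhi + 1, size=n)

    rng_pat = _rng(config.seed, _SECTION_PATTERNS)
    order = rng_pat.permutation(n)
    patterns = np.full(n, NULL_PATTERN, dtype=object)
    cursor = 0
    for pattern, frac in config.planted_fractions.items():
        count = int(np.floor(frac * n))
        patterns[order[cursor:cursor + count]] = pattern
        cursor += count

    signs = np.array([pattern_signs(p) for p in patterns])  # (n, 3)
    lfc = signs * config.effect_log2fc

    rng_drift = _rng(config.seed, _SECTION_DRIFT)
    drift = np.zeros((n, 3))
    if config.control_drift_fraction > 0:
        n_drift = int(np.floor(config.control_drift_fraction * n))
        drift_idx = rng_drift.choice(n, size=n_drift, replace=False)
        drift_sign = rng_drift.choice([-1.0, 1.0], size=n_drift)
        drift[drift_idx, :] = (drift_sign * config.control_drift_log2fc)[:, None]

    counts = {}
    count_seq = np.random.SeedSequence([config.seed, _SECTION_COUNTS])
    lib_rngs = [np.random.default_rng(s) for s in count_seq.spawn(7)]
    for lib, lib_rng in zip(DEFAULT_LIBRARIES, lib_rngs):
        if lib == "CK0":
            mean = baseline
        elif lib.startswith("CK"):
            t = int(lib[2:])
            mean = baseline * 2.0 ** drift[:, t - 1]
        else:
            t = int(lib[3:])
            mean = baseline * 2.0 ** (drift[:, t - 1] + lfc[:, t - 1])
        counts[lib] = _sample_counts(lib_rng, mean, config.dispersion)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id")),
        lengths=pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"),
                          name="length_bp"),
    )
    truth = SyntheticTruth(genes=pd.DataFrame({
        "gene_id": gene_ids,
        "pattern": patterns,
        "lfc_1d": lfc[:, 0], "lfc_2d": lfc[:, 1], "lfc_3d": lfc[:, 2],
        "drift_1d": drift[:, 0], "drift_2d": drift[:, 1], "drift_3d": drift[:, 2],
        "baseline_mean": baseline,
    }))
    return matrix, truth


def generate_annotation(config: SimConfig, truth: SyntheticTruth,
                        vocabulary: str = "GO-like"):
    """Draw one term vocabulary with planted enrichment.

    Enriched terms (the first ``n_enriched_terms`` ids) over-populate
    with planted non-null genes at ``enrichment_strength``; other terms
    draw members uniformly.  Records the enriched ids in
    ``truth.enriched_terms[vocabulary]`` and returns the AnnotationMap.
    """
    from .enrichment import AnnotationMap  # local import avoids a cycle

    ann = config.annotation
    ann.validate(config.n_genes)
    rng = _rng(config.seed, _SECTION_ANNOTATION,
               zlib.crc32(vocabulary.encode()))
    gene_ids = truth.genes["gene_id"].to_numpy()
    non_null = truth.non_null["gene_id"].to_numpy()
    prefix = vocabulary.split("-")[0].upper()

    lo, hi = ann.term_size_range
    sizes = rng.integers(lo, hi + 1, size=ann.n_terms)
    terms: dict[str, frozenset] = {}
    enriched_ids = []
    for i, size in enumerate(sizes):
        term_id = f"{prefix}:{i:04d}"
        if i < ann.n_enriched_terms and len(non_null) > 0:
            enriched_ids.append(term_id)
            n_planted = int(rng.binomial(size, ann.enrichment_strength))
            n_planted = min(n_planted, len(non_null))
            planted = rng.choice(non_null, size=n_planted, replace=False)
            rest_pool = np.setdiff1d(gene_ids, planted, assume_unique=False)
            rest = rng.choice(rest_pool, size=size - n_planted, replace=False)
            members = np.concatenate([planted, rest])
        else:
            members = rng.choice(gene_ids, size=size, replace=False)
        terms[term_id] = frozenset(members.tolist())
    truth.enriched_terms[vocabulary] = tuple(enriched_ids)
    return AnnotationMap(vocabulary=vocabulary, terms=terms)


def generate_ct_table(truth: SyntheticTruth, n_target_genes: int,
                      noise_sd: float = 0.2, seed: int = 0,
                      n_replicates: int = 3) -> pd.DataFrame:
    """Draw a Ct table for planted genes plus two reference genes.

    Targets are taken preferentially from planted genes with a day-1
    effect (mirroring validation panels that focus on the early
    response); each target's Ct at day t is its baseline Ct minus the
    planted log2 effect (one PCR cycle per two-fold change) plus
    Gaussian noise.  The references REF_EF1a and REF_GAPDH are constant
    in expectation.
    """
    if noise_sd < 0:
        raise SimConfigError("noise_sd must be >= 0")
    non_null = truth.non_null
    if n_target_genes > len(non_null):
        raise SimConfigError(
            f"n_target_genes={n_target_genes} exceeds the "
            f"{len(non_null)} planted genes")
    rng = _rng(seed, _SECTION_CT)
    early = non_null[non_null["lfc_1d"] != 0]
    late = non_null[non_null["lfc_1d"] == 0]
    pool = np.concatenate([
        rng.permutation(early["gene_id"].to_numpy()),
        rng.permutation(late["gene_id"].to_numpy()),
    ])
    target_ids = pool[:n_target_genes]
    lfc = truth.genes.set_index("gene_id")[["lfc_1d", "lfc_2d", "lfc_3d"]]

    samples = ("0d", "1d", "2d", "3d")
    references = {"REF_EF1a": 19.0, "REF_GAPDH": 21.0}
    rows = []
    base_cts = rng.uniform(22.0, 30.0, size=len(target_ids))
    for gene, base in zip(target_ids, base_cts):
        shifts = (0.0, *lfc.loc[gene].to_numpy())
        for sample, shift in zip(samples, shifts):
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "gene_id": gene, "sample": sample, "replicate": rep,
                    "ct": base - shift + rng.normal(0.0, noise_sd),
                    "is_reference": False,
                })
    for ref, base in references.items():
        for sample in samples:
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "gene_id": ref, "sample": sample, "replicate": rep,
                    "ct": base + rng.normal(0.0, noise_sd),
                    "is_reference": True,
                })
    return pd.DataFrame(rows)


def config_to_dict(config: SimConfig) -> dict:
    """JSON-serializable echo of a SimConfig (for report provenance)."""
    payload = asdict(config)
    payload["planted_fractions"] = dict(config.planted_fractions)
    return payload
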