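"""Duplication-event parsing and functional-term enrichment.

Enrichment uses the exact hypergeometric upper tail (scipy) with
Benjamini–Hochberg adjustment (statsmodels) across all tested terms, matching
the tooling choices the analyses are modeled on.  Terms are tested
independently; annotation inputs are assumed pre-propagated (slim-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DuplicationEvent",
    "EnrichmentResult",
    "read_duplication_table",
    "read_annotation_map",
    "parse_duplications",
    "hypergeometric_upper",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class DuplicationEvent:
    node_id: str
    orthogroup_id: str
    support: float
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.support <= 1.0):
            raise ValueError(f"support must be in [0, 1], got {self.support}")
        if not self.gene_ids:
            raise ValueError("gene list must be non-empty")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_hits: int  # k
    study_size: int  # n
    population_hits: int  # K
    population_size: int  # N
    p: float
    q: float
    significant: bool


def read_duplication_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Rows of (node, orthogroup, support, comma-joined genes) from TSV."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node"):
            raise ValueError("duplication table must start with a 'node' header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"expected 4 columns, got {len(fields)}")
            rows.append((fields[0], fields[1], fields[2], fields[3]))
    return rows


def read_annotation_map(path: str | Path) -> dict[str, frozenset[str]]:
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            gene, term = line.rstrip("\n").split("\t")
            annotations.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in annotations.items()}


def parse_duplications(
    rows: Iterable[tuple[str, str, str | float, str | Sequence[str]]],
    min_support: float = 0.90,
) -> dict[str, list[DuplicationEvent]]:
    """Keep events with clade support >= min_support (inclusive), grouped by node."""
    by_node: dict[str, list[DuplicationEvent]] = {}
    for node, og, support, genes in rows:
        try:
            value = float(support)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed support {support!r}") from exc
        if isinstance(genes, str):
            gene_ids = tuple(g for g in genes.split(",") if g)
        else:
            gene_ids = tuple(genes)
        event = DuplicationEvent(node, og, value, gene_ids)
        if event.support >= min_support:
            by_node.setdefault(node, []).append(event)
    return by_node


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn)."""
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValueError(f"k={k} exceeds annotated population K={K}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, order preserved, capped at 1."""
    if not len(p_values):
        return []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in q]


def enrich(
    study_genes: Iterable[str],
    annotation_map: Mapping[str, frozenset[str] | set[str]],
    population_genes: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One hypergeometric upper-tail test per term present in the study set,
    BH-adjusted across all tested terms; sorted by q then p then term."""
    study = set(study_genes)
    population = set(population_genes)
    missing = study - population
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)[:5]}")

    def terms_of(gene: str) -> frozenset[str]:
        return frozenset(annotation_map.get(gene, frozenset()))

    study_terms = sorted({t for g in study for t in terms_of(g)})
    N = len(population)
    n = len(study)
    results = []
    p_values = []
    for term in study_terms:
        K = sum(1 for g in population if term in terms_of(g))
        k = sum(1 for g in study if term in terms_of(g))
        p_values.append(hypergeometric_upper(k, K, n, N))
        results.append((term, k, K))
    q_values = bh_adjust(p_values)
    out = [
        EnrichmentResult(
            term=term,
            study_hits=k,
            study_size=n,
            population_hits=K,
            population_size=N,
            p=p,
            q=q,
            significant=q < alpha,
        )
        for (term, k, K), p, q in zip(results, p_values, q_values)
    ]
    out.sort(key=lambda r: (r.q, r.p, r.term))
    return out
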