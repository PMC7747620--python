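"""Gene-set over-representation analysis of the inferred target genes.

Upper-tail hypergeometric test of the overlap between the query gene list
and each annotated set, Benjamini-Hochberg adjustment within each collection
(GO, KEGG, Reactome supplied separately), top-term extraction, and the
Jaccard term-overlap matrix used to group related terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection

logger = logging.getLogger("mirsurv")

ADJ_P_CUTOFF = 0.05


@dataclass
class EnrichmentResult:
    collection: str
    term_id: str
    k: int              # overlap: query genes inside the set
    K: int              # set size within the universe
    n: int              # query size within the universe
    N: int              # universe size
    p_value: float
    adj_p: float = float("nan")
    significant: bool = False
    overlap_genes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"collection": self.collection, "term_id": self.term_id,
                "k": self.k, "K": self.K, "n": self.n, "N": self.N,
                "p_value": self.p_value, "adj_p": self.adj_p,
                "significant": self.significant,
                "overlap_genes": ",".join(self.overlap_genes)}


def hypergeom_ora(query_genes, gene_set, universe) -> tuple[int, float]:
    """Overlap count and upper-tail hypergeometric p-value P(X >= k).

    Query genes outside the universe are dropped with a warning; the set is
    intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("hypergeom_ora: empty universe")
    query = set(query_genes)
    if not query:
        raise ValueError("hypergeom_ora: empty query")
    outside = query - universe
    if outside:
        warnings.warn(f"hypergeom_ora: {len(outside)} query genes outside the "
                      "universe were dropped", stacklevel=2)
        query &= universe
        if not query:
            raise ValueError("hypergeom_ora: no query genes inside the universe")
    annotated = set(gene_set) & universe
    k = len(query & annotated)
    N, K, n = len(universe), len(annotated), len(query)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return k, min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("bh_adjust: p-values must lie in (0, 1]")
    return sps.false_discovery_control(p, method="bh")


def run_enrichment(query_genes, collections: dict[str, GeneSetCollection],
                   universe=None, adj_p_cutoff: float = ADJ_P_CUTOFF,
                   ) -> list[EnrichmentResult]:
    """ORA of the query against every set, BH-adjusted within each collection.

    ``universe`` overrides each collection's own universe (default background:
    all genes of the expression matrix the query was derived from).  Results
    are sorted by adjusted then raw p.
    """
    if not collections:
        raise ValueError("run_enrichment: no collections supplied")
    results: list[EnrichmentResult] = []
    for name, coll in collections.items():
        bg = set(universe) if universe is not None else coll.universe
        if bg is None:
            bg = set().union(*coll.sets.values())
        query = set(query_genes) & bg
        batch: list[EnrichmentResult] = []
        for term, genes in coll.sets.items():
            k, p = hypergeom_ora(query, genes, bg)
            batch.append(EnrichmentResult(
                collection=name, term_id=term, k=k,
                K=len(set(genes) & bg), n=len(query), N=len(bg), p_value=p,
                overlap_genes=tuple(sorted(query & set(genes)))))
        adj = bh_adjust([r.p_value for r in batch])
        for r, a in zip(batch, adj):
            r.adj_p = float(a)
            r.significant = r.adj_p < adj_p_cutoff
        results.extend(batch)
    results.sort(key=lambda r: (r.adj_p, r.p_value, r.term_id))
    return results


def top_terms(results: list[EnrichmentResult], n: int) -> list[EnrichmentResult]:
    """First n results by adjusted p (results are already sorted)."""
    if n > len(results):
        logger.warning("top_terms: requested %d terms, only %d available",
                       n, len(results))
    return results[:n]


def overlap_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Jaccard index of overlap genes for every pair of terms; diagonal 1."""
    ids = [r.term_id for r in results]
    sets = [set(r.overlap_genes) for r in results]
    m = np.eye(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            union = sets[i] | sets[j]
            m[i, j] = m[j, i] = (len(sets[i] & sets[j]) / len(union)
                                 if union else 0.0)
    return pd.DataFrame(m, index=ids, columns=ids)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
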