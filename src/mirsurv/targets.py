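"""Target-gene inference for signature miRNAs.

A candidate miRNA-gene interaction (from a validated-interaction database
and/or prediction-tool consensus) is accepted as a target when three
criteria hold simultaneously:

1. anti-correlation — at least one of Pearson, Spearman, Kendall tau-b
   between miRNA and gene expression falls below a negative threshold
   (default -0.3);
2. survival relevance — the gene's own median-split log-rank p is below
   threshold (direction-agnostic);
3. evidence — the interaction is database-validated, or called by at least
   ``min_tools`` of the 12 prediction tools (default 5, i.e. "more than
   four").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as mio
from .survival import DegenerateStratificationError, median_stratify, two_group_stats


@dataclass
class TargetConfig:
    correlation_threshold: float = -0.3
    target_p_threshold: float = 0.05
    min_tools: int = 5

    def __post_init__(self) -> None:
        if self.correlation_threshold >= 0:
            raise ValueError("correlation_threshold must be negative")
        if not 1 <= self.min_tools <= mio.MAX_TOOL_COUNT:
            raise ValueError(f"min_tools must lie in [1, {mio.MAX_TOOL_COUNT}]")

    def to_dict(self) -> dict:
        return {"correlation_threshold": self.correlation_threshold,
                "target_p_threshold": self.target_p_threshold,
                "min_tools": self.min_tools}


@dataclass
class TargetEvidence:
    mirna_id: str
    gene_id: str
    pearson: float
    spearman: float
    kendall: float
    target_logrank_p: float     # NaN if the gene split was degenerate
    validated: int
    tool_count: int
    passes: bool
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def min_correlation(self) -> float:
        return min(self.pearson, self.spearman, self.kendall)

    def to_dict(self) -> dict:
        return {
            "mirna_id": self.mirna_id, "gene_id": self.gene_id,
            "pearson": self.pearson, "spearman": self.spearman,
            "kendall": self.kendall, "min_correlation": self.min_correlation,
            "target_logrank_p": self.target_logrank_p,
            "validated": self.validated, "tool_count": self.tool_count,
            "passes": self.passes, "failure_reasons": ";".join(self.failure_reasons),
        }


def triple_correlation(x, y) -> tuple[float, float, float]:
    """Pearson, Spearman (average ranks) and Kendall tau-b for paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("triple_correlation: vectors must be paired 1-D")
    if x.size < 5:
        raise ValueError("triple_correlation: need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    pearson = float(sps.pearsonr(x, y).statistic)
    spearman = float(sps.spearmanr(x, y).statistic)
    kendall = float(sps.kendalltau(x, y, variant="b").statistic)
    return pearson, spearman, kendall


def infer_targets(mirna_ids: list[str], expr_mirna: pd.DataFrame,
                  expr_mrna: pd.DataFrame, clinical: pd.DataFrame,
                  evidence: pd.DataFrame, config: TargetConfig,
                  ) -> list[TargetEvidence]:
    """Apply the three target criteria to every relevant evidence row.

    Evidence rows are restricted to the queried miRNAs; genes absent from the
    mRNA matrix are skipped.  Every evaluated candidate is returned (with
    failure reasons) so the filter is auditable; the passing subset is the
    target list.
    """
    shared = [s for s in expr_mirna.columns
              if s in expr_mrna.columns and s in clinical.index]
    if not shared:
        raise mio.ValidationError("infer_targets: no shared samples across tables")
    expr_mirna = expr_mirna[shared]
    expr_mrna = expr_mrna[shared]
    clinical = clinical.loc[shared]

    ev = evidence[evidence["mirna_id"].isin(mirna_ids)
                  & evidence["gene_id"].isin(expr_mrna.index)]

    # gene-level survival p computed once per distinct gene
    gene_p: dict[str, float] = {}
    for gene in ev["gene_id"].unique():
        try:
            strat = median_stratify(expr_mrna.loc[gene], gene)
            gene_p[gene] = two_group_stats(clinical, strat).logrank_p
        except DegenerateStratificationError:
            gene_p[gene] = float("nan")

    out: list[TargetEvidence] = []
    for row in ev.itertuples(index=False):
        pear, spear, kend = triple_correlation(
            expr_mirna.loc[row.mirna_id].to_numpy(),
            expr_mrna.loc[row.gene_id].to_numpy())
        p = gene_p[row.gene_id]
        reasons: list[str] = []
        if not min(pear, spear, kend) < config.correlation_threshold:
            reasons.append("correlation")
        if not (np.isfinite(p) and p < config.target_p_threshold):
            reasons.append("survival")
        if not (row.validated == 1 or row.tool_count >= config.min_tools):
            reasons.append("insufficient evidence")
        out.append(TargetEvidence(
            mirna_id=row.mirna_id, gene_id=row.gene_id,
            pearson=pear, spearman=spear, kendall=kend,
            target_logrank_p=p, validated=int(row.validated),
            tool_count=int(row.tool_count),
            passes=not reasons, failure_reasons=reasons))
    return out


def passing_genes(targets: list[TargetEvidence]) -> list[str]:
    return sorted({t.gene_id for t in targets if t.passes})


@dataclass
class NetworkExport:
    edges: pd.DataFrame                 # mirna, gene, min_correlation, evidence_type
    per_mirna_counts: dict[str, int]
    shared_genes: list[str]             # genes targeted by more than one miRNA

    @property
    def overlap_count(self) -> int:
        return len(self.shared_genes)


def export_network(targets: list[TargetEvidence]) -> NetworkExport:
    """Edge list of passing miRNA-gene interactions plus overlap accounting."""
    passing = [t for t in targets if t.passes]
    edges = pd.DataFrame(
        [{"mirna": t.mirna_id, "gene": t.gene_id,
          "min_correlation": t.min_correlation,
          "evidence_type": "validated" if t.validated else "predicted"}
         for t in passing],
        columns=["mirna", "gene", "min_correlation", "evidence_type"])
    counts: dict[str, int] = {}
    gene_regulators: dict[str, set[str]] = {}
    for t in passing:
        counts[t.mirna_id] = counts.get(t.mirna_id, 0) + 1
        gene_regulators.setdefault(t.gene_id, set()).add(t.mirna_id)
    shared = sorted(g for g, regs in gene_regulators.items() if len(regs) > 1)
    return NetworkExport(edges=edges, per_mirna_counts=counts, shared_genes=shared)


def targets_to_frame(targets: list[TargetEvidence]) -> pd.DataFrame:
    return pd.DataFrame([t.to_dict() for t in targets])
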