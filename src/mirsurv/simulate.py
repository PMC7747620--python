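"""Synthetic TCGA-like cohorts with known ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes: per-miRNA log-normal expression (median-splittable), right-censored
survival times whose hazard follows a proportional-hazards model on the
high/low status of planted miRNAs — including pairwise interaction terms that
create genuine synergy — target genes linearly anti-correlated (on the log
scale) with their regulator miRNA, an interaction-evidence table with decoys,
and gene sets enriched for the planted targets.  Every output is a
deterministic function of the configuration and its seed.

Survival model: patient hazard is

    lambda = lambda0 * exp( sum_j beta_j z_j + sum_{j<k} gamma_jk z_j z_k )

with z_j = 1 iff the patient's log-expression of planted miRNA j exceeds that
feature's *population* median (the generation-time truth; the pipeline
re-estimates medians from data, a small intentional mismatch).  Event times
are exponential; censoring comes from an independent uniform horizon whose
upper bound is solved so that a null patient is censored at the target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GeneSetCollection, validate_evidence


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters; defaults give the standard test scenario."""

    n_patients: int = 300
    n_mirnas: int = 200
    n_genes: int = 1000
    baseline_hazard: float = 1.0 / 1500.0        # per day
    censor_rate: float = 0.7
    main_effects: dict[str, float] = field(default_factory=dict)       # miRNA -> beta
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    # expression model (log scale)
    log_mu_mean: float = 3.0
    log_mu_sd: float = 1.5
    log_sigma_range: tuple[float, float] = (0.5, 1.5)
    low_expression_fraction: float = 0.1          # features with mean RPM < 1
    planted_log_mu: float = 3.0
    planted_log_sigma: float = 1.0
    # mRNA / target model
    target_map: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    #                 gene -> (regulator miRNA, slope b < 0, noise sd)
    mrna_intercept: float = 8.0
    # evidence table
    evidence_decoy_rate: float = 1.0              # decoy rows per true target
    evidence_miss_rate: float = 0.0               # true targets given weak evidence
    evidence_min_tools: int = 5
    # gene sets
    planted_sets: dict[str, float] = field(default_factory=dict)  # name -> true-target fraction
    geneset_size: int = 50
    n_random_sets: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 < self.censor_rate < 1:
            raise ValueError("censor_rate must lie in (0, 1)")
        for gene, (_, slope, _) in self.target_map.items():
            if slope > 0:
                raise ValueError(f"planted target {gene!r} needs a non-positive slope")

    @property
    def planted_mirnas(self) -> list[str]:
        names = list(self.main_effects)
        for a, b in self.interaction_effects:
            for m in (a, b):
                if m not in names:
                    names.append(m)
        return names


@dataclass
class GroundTruth:
    """Answer key for recovery tests."""

    prognostic_mirnas: list[str]
    synergistic_pairs: list[tuple[str, str]]
    targets_by_mirna: dict[str, list[str]]
    enriched_sets: list[str]
    censor_horizon: float

    @property
    def all_targets(self) -> list[str]:
        out: list[str] = []
        for genes in self.targets_by_mirna.values():
            out.extend(genes)
        return sorted(set(out))

    def to_dict(self) -> dict:
        return {
            "prognostic_mirnas": self.prognostic_mirnas,
            "synergistic_pairs": [list(p) for p in self.synergistic_pairs],
            "targets_by_mirna": self.targets_by_mirna,
            "enriched_sets": self.enriched_sets,
            "censor_horizon": self.censor_horizon,
        }


def censor_horizon(baseline_hazard: float, censor_rate: float) -> float:
    """Upper bound H of the uniform censoring time.

    For an exponential(lambda0) event time and C ~ U(0, H) the censoring
    probability is E[exp(-lambda0 C)] = (1 - exp(-lambda0 H)) / (lambda0 H),
    which decreases from 1 to 0 in H; solve it at the target rate.
    """
    lam = baseline_hazard

    def f(h):
        x = lam * h
        return -np.expm1(-x) / x - censor_rate

    return float(brentq(f, 1e-6 / lam, 1e4 / lam))


def simulate_cohort(config: SyntheticConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the miRNA expression matrix, clinical table and ground truth."""
    expected_events = config.n_patients * (1.0 - config.censor_rate)
    if expected_events < 10:
        raise ValueError(
            f"configuration implies ~{expected_events:.1f} expected events; "
            "fewer than 10 cannot support survival estimation")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    planted = config.planted_mirnas
    if len(planted) > config.n_mirnas:
        raise ValueError("more planted miRNAs than n_mirnas")

    n_null = config.n_mirnas - len(planted)
    mirna_ids = planted + [f"miR-sim-{i:04d}" for i in range(n_null)]

    mu = np.empty(config.n_mirnas)
    sigma = np.empty(config.n_mirnas)
    mu[:len(planted)] = config.planted_log_mu
    sigma[:len(planted)] = config.planted_log_sigma
    mu[len(planted):] = rng.normal(config.log_mu_mean, config.log_mu_sd, n_null)
    sigma[len(planted):] = rng.uniform(*config.log_sigma_range, n_null)
    # push a fraction of null features below the RPM filter
    n_low = int(round(config.low_expression_fraction * n_null))
    if n_low:
        low_idx = len(planted) + rng.choice(n_null, size=n_low, replace=False)
        mu[low_idx] = -3.0

    log_expr = rng.normal(mu[:, None], sigma[:, None],
                          size=(config.n_mirnas, config.n_patients))
    expr = pd.DataFrame(np.exp(log_expr), index=mirna_ids,
                        columns=[f"P{i:04d}" for i in range(config.n_patients)])

    # high/low status against the population (not sample) median: exp(mu_j)
    z = {m: (log_expr[i] > mu[i]).astype(float)
         for i, m in enumerate(planted)}
    log_rel_hazard = np.zeros(config.n_patients)
    for m, beta in config.main_effects.items():
        log_rel_hazard += beta * z[m]
    for (a, b), gamma in config.interaction_effects.items():
        log_rel_hazard += gamma * z[a] * z[b]
    lam = config.baseline_hazard * np.exp(log_rel_hazard)

    t_event = rng.exponential(1.0 / lam)
    horizon = censor_horizon(config.baseline_hazard, config.censor_rate)
    t_censor = rng.uniform(0.0, horizon, config.n_patients)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    clinical = pd.DataFrame({"time": time, "event": event}, index=expr.columns)
    clinical.index.name = "sample_id"

    truth = GroundTruth(
        prognostic_mirnas=list(planted),
        synergistic_pairs=[tuple(sorted(p)) for p in config.interaction_effects],
        targets_by_mirna={m: sorted(g for g, (reg, _, _) in config.target_map.items()
                                    if reg == m) for m in planted},
        enriched_sets=list(config.planted_sets),
        censor_horizon=horizon,
    )
    return expr, clinical, truth


def simulate_targets(config: SyntheticConfig, expr_mirna: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate the mRNA matrix: planted targets track their regulator.

    A planted gene is ``intercept + slope * log(regulator) + noise``; other
    genes are independent log-normal.  Returns the matrix and, for each
    planted gene, the achieved Pearson correlation between the gene and the
    regulator's log expression (the scale on which the link is linear).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_patients = expr_mirna.shape[1]
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    planted = dict(config.target_map)
    missing = [g for g in planted if g not in gene_ids]
    if missing:
        raise ValueError(f"target_map genes outside the gene id space: {missing}")
    for _, (reg, _, _) in planted.items():
        if reg not in expr_mirna.index:
            raise ValueError(f"regulator {reg!r} absent from the miRNA matrix")

    values = np.empty((config.n_genes, n_patients))
    achieved: dict[str, float] = {}
    mu_g = rng.normal(2.0, 1.0, config.n_genes)
    for i, gene in enumerate(gene_ids):
        if gene in planted:
            reg, slope, noise_sd = planted[gene]
            logx = np.log(expr_mirna.loc[reg].to_numpy())
            y = config.mrna_intercept + slope * logx + rng.normal(0, noise_sd,
                                                                  n_patients)
            values[i] = np.clip(y, 0.0, None)
            achieved[gene] = float(np.corrcoef(logx, values[i])[0, 1])
        else:
            values[i] = np.exp(rng.normal(mu_g[i], 1.0, n_patients))
    expr_mrna = pd.DataFrame(values, index=gene_ids, columns=expr_mirna.columns)
    return expr_mrna, achieved


def make_evidence(config: SyntheticConfig, truth: GroundTruth) -> pd.DataFrame:
    """Interaction-evidence table: true targets get strong evidence (validated
    or high tool consensus), with configurable decoy rows (non-targets with
    strong evidence) and missed targets (true pairs with weak evidence)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    non_targets = sorted(set(gene_ids) - set(truth.all_targets))
    rows = []
    n_true = 0
    for mirna, genes in truth.targets_by_mirna.items():
        for gene in genes:
            n_true += 1
            if rng.random() < config.evidence_miss_rate:
                rows.append((mirna, gene, 0, int(rng.integers(0, config.evidence_min_tools))))
            elif rng.random() < 0.5:
                rows.append((mirna, gene, 1, int(rng.integers(0, 13))))
            else:
                rows.append((mirna, gene, 0,
                             int(rng.integers(config.evidence_min_tools, 13))))
    n_decoys = int(round(config.evidence_decoy_rate * n_true))
    planted = truth.prognostic_mirnas
    if n_decoys and planted and non_targets:
        decoy_genes = rng.choice(non_targets, size=min(n_decoys, len(non_targets)),
                                 replace=False)
        for gene in decoy_genes:
            mirna = planted[int(rng.integers(len(planted)))]
            rows.append((mirna, str(gene), int(rng.random() < 0.5),
                         int(rng.integers(config.evidence_min_tools, 13))))
    ev = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "validated",
                                     "tool_count"])
    ev = ev.drop_duplicates(subset=["mirna_id", "gene_id"])
    return validate_evidence(ev.reset_index(drop=True))


def make_genesets(config: SyntheticConfig, truth: GroundTruth) -> GeneSetCollection:
    """Gene sets: each planted set holds a stated fraction of true targets,
    topped up with random non-targets; plus random background sets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    universe = set(gene_ids)
    non_targets = sorted(universe - set(truth.all_targets))
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for name, frac in config.planted_sets.items():
        n_true = min(int(round(frac * config.geneset_size)),
                     len(truth.all_targets))
        true_part = rng.choice(truth.all_targets, size=n_true, replace=False)
        filler = rng.choice(non_targets, size=config.geneset_size - n_true,
                            replace=False)
        sets[name] = set(map(str, true_part)) | set(map(str, filler))
        descriptions[name] = f"synthetic set enriched for planted targets ({frac:.0%})"
    for i in range(config.n_random_sets):
        name = f"RANDOM_SET_{i:02d}"
        sets[name] = set(map(str, rng.choice(gene_ids, size=config.geneset_size,
                                             replace=False)))
        descriptions[name] = "synthetic background set"
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             universe=universe)


def default_scenario(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard recovery scenario: three prognostic miRNAs (named after a
    published cervical-cancer signature) with pairwise synergy, twenty planted
    target genes each, and one gene set enriched for those targets."""
    trio = ["miR-216b-5p", "miR-585-5p", "miR-7641"]
    beta = float(np.log(1.3))
    gamma = float(np.log(2.0))
    target_map = {}
    for j, m in enumerate(trio):
        for i in range(20):
            target_map[f"G{j * 20 + i:04d}"] = (m, -0.8, 0.3)
    cfg = dict(
        main_effects={m: beta for m in trio},
        interaction_effects={(a, b): gamma
                             for a, b in [(trio[0], trio[1]),
                                          (trio[0], trio[2]),
                                          (trio[1], trio[2])]},
        target_map=target_map,
        planted_sets={"PLANTED_SET": 0.8},
        seed=seed,
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def null_scenario(seed: int = 0, **overrides) -> SyntheticConfig:
    """No planted effects: expression independent of survival."""
    cfg = dict(main_effects={}, interaction_effects={}, target_map={},
               planted_sets={}, seed=seed)
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def simulate_all(config: SyntheticConfig):
    """Cohort + mRNA + evidence + gene sets + truth in one call."""
    expr_mirna, clinical, truth = simulate_cohort(config)
    expr_mrna, achieved = simulate_targets(config, expr_mirna)
    evidence = make_evidence(config, truth)
    genesets = make_genesets(config, truth)
    return {
        "expr_mirna": expr_mirna, "clinical": clinical,
        "expr_mrna": expr_mrna, "evidence": evidence,
        "genesets": genesets, "truth": truth,
        "achieved_target_correlation": achieved,
    }
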