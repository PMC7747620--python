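"""Three-stage prognostic miRNA discovery cascade.

Stage 1 (oncomiR screen): every miRNA is median-split and kept if its
high-expression group has worse survival (log-rank p below threshold, Cox
HR above 1) and the miRNA is expressed at all (mean RPM above threshold).

Stage 2 (synergy screen): every unordered pair of passing miRNAs is split
into all-high vs all-low patients; a pair is synergistic when its combined
HR exceeds a fold multiple (default 1.5x) of *each* member's single HR,
again with a significant log-rank test.

Stage 3 (additive search): every subset of the synergy-surviving miRNAs is
evaluated the same way; stacking more signature miRNAs should push the
all-high/all-low hazard ratio up, and the best combination is the
maximum-HR subset among those that remain significant with adequately
sized groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import (
    DegenerateStratificationError,
    Stratification,
    SurvivalStats,
    combo_stratify,
    median_stratify,
    two_group_stats,
)

MAX_SELECTED = 25  # combinatorial guard: 2^25 subsets is already absurd


@dataclass
class ScreenConfig:
    """Thresholds of the discovery cascade.

    p_threshold / hr_threshold gate the single-miRNA screen and every
    combination; rpm_threshold drops barely-expressed miRNAs (mean RPM);
    synergy_fold is the pair-over-single HR multiple; min_group_size guards
    against inflated HRs from tiny all-high or all-low groups.
    """

    p_threshold: float = 0.05
    hr_threshold: float = 1.0
    rpm_threshold: float = 1.0
    synergy_fold: float = 1.5
    max_combo_size: int | None = None
    min_group_size: int = 10
    seed: int = 0
    bh_correct: bool = False   # off by default: raw log-rank p thresholds

    def __post_init__(self) -> None:
        if min(self.p_threshold, self.hr_threshold, self.rpm_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.synergy_fold <= 1:
            raise ValueError("synergy_fold must exceed 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "p_threshold", "hr_threshold", "rpm_threshold", "synergy_fold",
            "max_combo_size", "min_group_size", "seed", "bh_correct")}


@dataclass
class OncomiRRecord:
    mirna_id: str
    mean_rpm: float
    stats: SurvivalStats | None
    passes: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"mirna_id": self.mirna_id, "mean_rpm": self.mean_rpm,
             "passes": self.passes, "reasons": ";".join(self.reasons)}
        if self.stats is not None:
            d.update(self.stats.to_dict())
        return d


@dataclass
class SynergyPair:
    mirna_a: str
    mirna_b: str
    pair_stats: SurvivalStats | None
    hr_a: float
    hr_b: float
    passes: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"mirna_a": self.mirna_a, "mirna_b": self.mirna_b,
             "hr_a": self.hr_a, "hr_b": self.hr_b,
             "passes": self.passes, "reasons": ";".join(self.reasons)}
        if self.pair_stats is not None:
            d.update({f"pair_{k}": v for k, v in self.pair_stats.to_dict().items()})
        return d


@dataclass
class ComboResult:
    mirna_set: tuple[str, ...]
    k: int
    stats: SurvivalStats | None
    log2_hr: float | None
    degenerate: bool
    reason: str = ""

    def to_dict(self) -> dict:
        d = {"mirnas": ",".join(self.mirna_set), "k": self.k,
             "log2_hr": self.log2_hr, "degenerate": self.degenerate,
             "reason": self.reason}
        if self.stats is not None:
            d.update(self.stats.to_dict())
        return d


# ---------------------------------------------------------------------------
# stage 1: oncomiR screen
# ---------------------------------------------------------------------------

def screen_oncomirs(expr_mirna: pd.DataFrame, clinical: pd.DataFrame,
                    config: ScreenConfig) -> list[OncomiRRecord]:
    """Median-split survival screen over every miRNA row.

    Returns one record per miRNA (failures carry reasons, nothing is raised
    per-row); passing records come first, sorted by log-rank p ascending.
    """
    if expr_mirna.shape[1] < 4:
        raise ValueError("screen_oncomirs needs at least 4 samples")
    records: list[OncomiRRecord] = []
    for mirna_id, row in expr_mirna.iterrows():
        mean_rpm = float(row.mean())
        reasons: list[str] = []
        stats: SurvivalStats | None = None
        if mean_rpm <= config.rpm_threshold:
            reasons.append("low expression")
        try:
            strat = median_stratify(row, mirna_id)
            stats = two_group_stats(clinical, strat)
        except DegenerateStratificationError:
            reasons.append("degenerate stratification")
        if stats is not None:
            if not stats.logrank_p < config.p_threshold:
                reasons.append("not significant")
            if not stats.hr > config.hr_threshold:
                reasons.append("HR not above threshold")
        records.append(OncomiRRecord(
            mirna_id=str(mirna_id), mean_rpm=mean_rpm, stats=stats,
            passes=not reasons, reasons=reasons))
    records.sort(key=lambda r: (not r.passes,
                                r.stats.logrank_p if r.stats else math.inf,
                                r.mirna_id))
    return records


def passing_oncomirs(records: list[OncomiRRecord]) -> list[str]:
    return [r.mirna_id for r in records if r.passes]


# ---------------------------------------------------------------------------
# stage 2: synergy screen
# ---------------------------------------------------------------------------

def synergy_criterion(pair_hr: float, hr_a: float, hr_b: float, pair_p: float,
                      config: ScreenConfig) -> bool:
    """The pair rule: combined HR strictly above ``synergy_fold`` times each
    single HR, with a significant log-rank p."""
    return (pair_hr > config.synergy_fold * hr_a
            and pair_hr > config.synergy_fold * hr_b
            and pair_p < config.p_threshold)


def synergy_screen(passing_ids: list[str], expr_mirna: pd.DataFrame,
                   clinical: pd.DataFrame, config: ScreenConfig,
                   single_stats: dict[str, SurvivalStats] | None = None,
                   ) -> list[SynergyPair]:
    """Evaluate every unordered pair of screen survivors for synergy.

    ``single_stats`` (from the oncomiR screen) avoids refitting singles;
    missing entries are fitted here.  All-high vs all-low patients only;
    pairs whose groups are empty or below ``min_group_size`` are flagged,
    not raised.
    """
    if len(passing_ids) < 2:
        raise ValueError("synergy_screen needs at least two passing miRNAs")
    strats: dict[str, Stratification] = {}
    singles: dict[str, SurvivalStats] = dict(single_stats or {})
    for mid in passing_ids:
        strats[mid] = median_stratify(expr_mirna.loc[mid], mid)
        if mid not in singles:
            singles[mid] = two_group_stats(clinical, strats[mid])

    pairs: list[SynergyPair] = []
    for a, b in itertools.combinations(passing_ids, 2):
        combo = combo_stratify({a: strats[a], b: strats[b]})
        reasons: list[str] = []
        stats: SurvivalStats | None = None
        if combo.degenerate:
            reasons.append("degenerate: empty all-high or all-low group")
        elif min(combo.n_high, combo.n_low) < config.min_group_size:
            reasons.append("group below min_group_size")
        else:
            stats = two_group_stats(clinical, combo)
            if not synergy_criterion(stats.hr, singles[a].hr, singles[b].hr,
                                     stats.logrank_p, config):
                reasons.append("synergy criterion not met")
        pairs.append(SynergyPair(
            mirna_a=a, mirna_b=b, pair_stats=stats,
            hr_a=singles[a].hr, hr_b=singles[b].hr,
            passes=not reasons, reasons=reasons))
    return pairs


def synergy_union(pairs: list[SynergyPair]) -> list[str]:
    """Sorted union of miRNAs across passing pairs — the signature candidates."""
    out: set[str] = set()
    for p in pairs:
        if p.passes:
            out.update((p.mirna_a, p.mirna_b))
    return sorted(out)


# ---------------------------------------------------------------------------
# stage 3: additive combination search
# ---------------------------------------------------------------------------

def additive_search(selected: list[str], expr_mirna: pd.DataFrame,
                    clinical: pd.DataFrame, config: ScreenConfig,
                    ) -> list[ComboResult]:
    """All-high vs all-low survival stats for every non-empty subset.

    Degenerate combinations (empty group, or a group below min_group_size)
    are retained in the output with a flag so combination-size distributions
    can be drawn with or without them.
    """
    if len(selected) > MAX_SELECTED:
        raise ValueError(
            f"{len(selected)} selected miRNAs imply 2^{len(selected)} subsets; "
            "set max_combo_size or shrink the selection")
    max_k = config.max_combo_size or len(selected)
    strats = {m: median_stratify(expr_mirna.loc[m], m) for m in selected}
    combos: list[ComboResult] = []
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(sorted(selected), k):
            combo = combo_stratify({m: strats[m] for m in subset})
            if combo.degenerate:
                combos.append(ComboResult(subset, k, None, None, True,
                                          "empty all-high or all-low group"))
                continue
            stats = two_group_stats(clinical, combo)
            degenerate = min(combo.n_high, combo.n_low) < config.min_group_size
            combos.append(ComboResult(
                subset, k, stats, float(np.log2(stats.hr)), degenerate,
                "group below min_group_size" if degenerate else ""))
    return combos


def select_best(combos: list[ComboResult], config: ScreenConfig,
                ) -> tuple[ComboResult | None, dict]:
    """Maximum-HR qualifying combination.

    Qualifying: non-degenerate, log-rank p below threshold, HR above
    threshold, both groups at least ``min_group_size``.  Ties break toward
    smaller p, then smaller subset, then lexicographic miRNA ids.  Returns
    (best or None, report).
    """
    if not combos:
        raise ValueError("select_best: no combinations supplied")
    qualifying = [
        c for c in combos
        if not c.degenerate and c.stats is not None
        and c.stats.logrank_p < config.p_threshold
        and c.stats.hr > config.hr_threshold
        and min(c.stats.n_high, c.stats.n_low) >= config.min_group_size
    ]
    report = {"n_combos": len(combos), "n_qualifying": len(qualifying)}
    if not qualifying:
        report["reason"] = "no significant combination"
        return None, report
    best = min(qualifying,
               key=lambda c: (-c.stats.hr, c.stats.logrank_p, c.k, c.mirna_set))
    report["best"] = list(best.mirna_set)
    return best, report


def combos_to_frame(combos: list[ComboResult]) -> pd.DataFrame:
    """Flat table (one row per combination) for export/plotting: k vs log2 HR."""
    return pd.DataFrame([c.to_dict() for c in combos])
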