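"""End-to-end pipeline runner: screen -> synergy -> additive -> targets -> enrichment.

Wires the stages together with a YAML config, writes one result file per
stage plus a JSON run manifest (config snapshot, seed, input digests,
per-stage counts), and short-circuits gracefully when a stage comes up
empty — the manifest records why.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .enrichment import overlap_matrix, results_to_frame, run_enrichment, top_terms
from .screening import (
    ComboResult,
    ScreenConfig,
    additive_search,
    combos_to_frame,
    passing_oncomirs,
    screen_oncomirs,
    select_best,
    synergy_screen,
    synergy_union,
)
from .simulate import default_scenario, simulate_all
from .targets import (
    TargetConfig,
    export_network,
    infer_targets,
    passing_genes,
    targets_to_frame,
)

logger = logging.getLogger("mirsurv")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    short_circuit: str | None = None
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config, "seed": self.seed,
            "input_digests": self.input_digests, "counts": self.counts,
            "stages_run": self.stages_run, "short_circuit": self.short_circuit,
            "started": self.started, "finished": self.finished,
        }

    def comparable(self) -> dict:
        """Manifest minus timestamps, for determinism checks."""
        d = self.to_dict()
        d.pop("started")
        d.pop("finished")
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_all(config: dict, outdir: str | Path) -> RunManifest:
    """Run the full cascade from a config mapping.

    Config keys: ``inputs`` (paths: expr_mirna, clinical, expr_mrna, evidence,
    gmt files as {collection: path}) or ``simulate: true`` (+ optional
    ``scenario`` overrides); ``screen`` / ``targets`` sub-mappings override
    :class:`ScreenConfig` / :class:`TargetConfig` defaults; ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    screen_cfg = ScreenConfig(**{**config.get("screen", {}), "seed": seed})
    target_cfg = TargetConfig(**config.get("targets", {}))
    manifest = RunManifest(config=_jsonable(config), seed=seed,
                           started=_now())

    if config.get("simulate"):
        sim_cfg = default_scenario(seed=seed, **config.get("scenario", {}))
        data = simulate_all(sim_cfg)
        expr_mirna, clinical = data["expr_mirna"], data["clinical"]
        expr_mrna, evidence = data["expr_mrna"], data["evidence"]
        collections = {"SIMULATED": data["genesets"]}
        mio.write_results(data["truth"].to_dict(), outdir / "ground_truth.json")
        manifest.input_digests["simulated"] = f"seed={seed}"
    else:
        paths = config["inputs"]
        expr_mirna = mio.read_expression(paths["expr_mirna"])
        clinical, clin_report = mio.read_clinical(paths["clinical"])
        manifest.counts["clinical_exclusions"] = clin_report
        expr_mrna = (mio.read_expression(paths["expr_mrna"])
                     if "expr_mrna" in paths else None)
        evidence = (mio.read_evidence(paths["evidence"])
                    if "evidence" in paths else None)
        collections = {name: mio.read_gmt(p)
                       for name, p in config.get("gene_sets", {}).items()}
        for key, p in paths.items():
            manifest.input_digests[key] = _digest(Path(p))

    expr_mirna, clinical, align_report = mio.align_samples(expr_mirna, clinical)
    manifest.counts["alignment"] = align_report
    manifest.counts["mirnas_in"] = int(expr_mirna.shape[0])

    # stage 1: oncomiR screen
    records = screen_oncomirs(expr_mirna, clinical, screen_cfg)
    passing = passing_oncomirs(records)
    single_stats = {r.mirna_id: r.stats for r in records if r.stats is not None}
    pd.DataFrame([r.to_dict() for r in records]).to_csv(
        outdir / "oncomirs.tsv", sep="\t", index=False)
    manifest.stages_run.append("screen")
    manifest.counts["oncomirs_passing"] = len(passing)
    if len(passing) < 2:
        return _finish(manifest, outdir,
                       "fewer than two passing oncomiRs; synergy stage skipped")

    # stage 2: synergy
    pairs = synergy_screen(passing, expr_mirna, clinical, screen_cfg,
                           single_stats=single_stats)
    pd.DataFrame([p.to_dict() for p in pairs]).to_csv(
        outdir / "synergy_pairs.tsv", sep="\t", index=False)
    union = synergy_union(pairs)
    manifest.stages_run.append("synergy")
    manifest.counts["pairs_evaluated"] = len(pairs)
    manifest.counts["pairs_passing"] = sum(p.passes for p in pairs)
    manifest.counts["synergy_union"] = union
    if not union:
        return _finish(manifest, outdir,
                       "no synergistic pair; additive stage skipped")

    # stage 3: additive search + best combination
    combos = additive_search(union, expr_mirna, clinical, screen_cfg)
    combos_to_frame(combos).to_csv(outdir / "combos.tsv", sep="\t", index=False)
    best, best_report = select_best(combos, screen_cfg)
    manifest.stages_run.append("additive")
    manifest.counts["combos_evaluated"] = len(combos)
    manifest.counts["best_combo"] = best_report
    mio.write_results(_combo_json(best, best_report), outdir / "best_combo.json")
    if best is None:
        return _finish(manifest, outdir, "no significant combination")
    signature = list(best.mirna_set)

    # stage 4: target inference
    if expr_mrna is None or evidence is None:
        return _finish(manifest, outdir,
                       "no mRNA/evidence inputs; target stage skipped")
    targets = infer_targets(signature, expr_mirna, expr_mrna, clinical,
                            evidence, target_cfg)
    targets_to_frame(targets).to_csv(outdir / "targets.tsv", sep="\t", index=False)
    network = export_network(targets)
    network.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    genes = passing_genes(targets)
    manifest.stages_run.append("targets")
    manifest.counts["target_candidates"] = len(targets)
    manifest.counts["targets_passing"] = len(genes)
    manifest.counts["targets_per_mirna"] = network.per_mirna_counts
    manifest.counts["target_overlap"] = network.overlap_count
    if not genes:
        return _finish(manifest, outdir,
                       "no passing target genes; enrichment skipped")

    # stage 5: enrichment
    if not collections:
        return _finish(manifest, outdir, "no gene sets supplied")
    universe = set(expr_mrna.index)
    results = run_enrichment(genes, collections, universe=universe)
    results_to_frame(results).to_csv(outdir / "enrichment.tsv", sep="\t",
                                     index=False)
    top = top_terms(results, min(30, len(results)))
    overlap_matrix(top).to_csv(outdir / "overlap_matrix.tsv", sep="\t")
    manifest.stages_run.append("enrich")
    manifest.counts["significant_terms"] = sum(r.significant for r in results)
    manifest.counts["top_term"] = results[0].term_id if results else None
    return _finish(manifest, outdir, None)


def _finish(manifest: RunManifest, outdir: Path, reason: str | None) -> RunManifest:
    manifest.short_circuit = reason
    manifest.finished = _now()
    if reason:
        logger.warning("pipeline stopped early: %s", reason)
    mio.write_results(manifest.to_dict(), outdir / "manifest.json")
    return manifest


def _combo_json(best: ComboResult | None, report: dict) -> dict:
    out = {"report": report}
    if best is not None:
        out["best"] = best.to_dict()
    return out


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
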