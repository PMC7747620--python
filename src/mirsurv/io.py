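"""Readers and writers for the pipeline's external table formats.

Expression matrices, clinical tables and miRNA-gene evidence tables travel as
TSV (GDC-style); gene sets as GMT; results as TSV or JSON.  All readers
validate the invariants the downstream statistics rely on (unique ids, finite
non-negative expression, binary event indicators) and log what they read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("mirsurv")

MAX_TOOL_COUNT = 12


class ParseError(ValueError):
    """A cell or line could not be interpreted; the message names it."""


class ValidationError(ValueError):
    """A structurally valid file violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression(df: pd.DataFrame, *, nonnegative: bool = True) -> pd.DataFrame:
    """Check ExpressionMatrix invariants: unique ids, finite values, >= 0."""
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"non-finite value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if nonnegative and (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative expression at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def read_expression(
    path: str | Path,
    orientation: str = "features_in_rows",
    sep: str = "\t",
    nonnegative: bool = True,
) -> pd.DataFrame:
    """Read a feature-by-sample expression matrix from TSV.

    The first column holds feature ids and the header row sample ids (flip
    with ``orientation="samples_in_rows"``).  Non-numeric cells are a parse
    error naming the offending feature and sample.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if orientation == "samples_in_rows":
        raw = raw.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: cannot parse value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    numeric = validate_expression(numeric.astype(float), nonnegative=nonnegative)
    logger.info("read_expression: %d features x %d samples from %s",
                numeric.shape[0], numeric.shape[1], path)
    return numeric


def write_expression(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="feature_id")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

REQUIRED_CLINICAL = ("sample_id", "time", "event")


def read_clinical(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, dict]:
    """Read a clinical table: sample_id, follow-up time (days), event (0/1).

    Rows with missing or non-positive time, or missing event, are dropped and
    counted in the returned exclusion report.  An event value outside {0, 1}
    is an error (it signals a mis-coded file, not a missing observation).
    """
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    missing = [c for c in REQUIRED_CLINICAL if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    if raw["sample_id"].duplicated().any():
        dups = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")

    time = pd.to_numeric(raw["time"], errors="coerce")
    event = pd.to_numeric(raw["event"], errors="coerce")
    bad_event = event.dropna()[~event.dropna().isin([0, 1])]
    if len(bad_event):
        raise ValidationError(
            f"{path}: event must be 0 or 1, got {bad_event.iloc[0]} "
            f"for sample {raw.loc[bad_event.index[0], 'sample_id']!r}"
        )
    keep = time.notna() & (time > 0) & event.notna()
    report = {
        "n_read": int(len(raw)),
        "n_kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
        "dropped_missing_or_nonpositive_time": int((time.isna() | (time <= 0)).sum()),
        "dropped_missing_event": int((event.isna() & time.notna() & (time > 0)).sum()),
    }
    clin = raw.loc[keep].copy()
    clin["time"] = time[keep].astype(float)
    clin["event"] = event[keep].astype(int)
    clin = clin.set_index("sample_id")
    logger.info("read_clinical: kept %d/%d rows from %s",
                report["n_kept"], report["n_read"], path)
    return clin, report


def write_clinical(clin: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    clin.to_csv(path, sep=sep, index_label="sample_id")


def align_samples(
    expr: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Restrict expression and clinical tables to their shared samples.

    Both outputs use the same sample order (expression column order).  An
    empty intersection is an error; samples present in only one table are
    counted in the report so cohort attrition stays auditable.
    """
    shared = [s for s in expr.columns if s in clinical.index]
    if not shared:
        raise ValidationError("align_samples: no samples shared between tables")
    report = {
        "n_shared": len(shared),
        "expr_only": int(len(expr.columns) - len(shared)),
        "clinical_only": int(len(clinical.index) - len(shared)),
    }
    logger.info("align_samples: %(n_shared)d shared, %(expr_only)d expression-only, "
                "%(clinical_only)d clinical-only", report)
    return expr[shared], clinical.loc[shared], report


def _round_half_even(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1") ** ndigits,
                                           rounding=ROUND_HALF_EVEN))


def format_percent(count: int, total: int) -> str:
    """Percentage of total at one decimal, round-half-even, trailing .0 trimmed."""
    pct = _round_half_even(100.0 * count / total, 1)
    s = f"{pct:.1f}"
    if s.endswith(".0"):
        s = s[:-2]
    return f"{s}%"


def summarize_clinical(
    clinical: pd.DataFrame, total_n: int | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category counts and percentages for categorical covariate columns.

    Mirrors a cohort-description table: each category's count and its share
    of ``total_n`` (default: number of rows) to one decimal.
    """
    if total_n is None:
        total_n = len(clinical)
    if covariates is None:
        covariates = [c for c in clinical.columns
                      if c not in ("time", "event")
                      and not pd.api.types.is_numeric_dtype(clinical[c])]
    rows = []
    for cov in covariates:
        counts = clinical[cov].value_counts(dropna=False)
        for category, count in counts.items():
            rows.append({
                "variable": cov,
                "category": str(category),
                "count": int(count),
                "percent": _round_half_even(100.0 * count / total_n, 1),
                "percent_str": format_percent(int(count), total_n),
            })
    return pd.DataFrame(rows, columns=["variable", "category", "count",
                                       "percent", "percent_str"])


# ---------------------------------------------------------------------------
# evidence tables and gene sets
# ---------------------------------------------------------------------------

def read_evidence(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a miRNA-gene interaction evidence table.

    Columns: mirna_id, gene_id, validated (0/1, database-recorded), tool_count
    (how many of the 12 prediction tools call the interaction).
    """
    ev = pd.read_csv(path, sep=sep, dtype={"mirna_id": str, "gene_id": str})
    return validate_evidence(ev)


def validate_evidence(ev: pd.DataFrame) -> pd.DataFrame:
    required = ("mirna_id", "gene_id", "validated", "tool_count")
    missing = [c for c in required if c not in ev.columns]
    if missing:
        raise ValidationError(f"evidence table missing column(s) {missing}")
    if ev.duplicated(subset=["mirna_id", "gene_id"]).any():
        dup = ev.loc[ev.duplicated(subset=["mirna_id", "gene_id"]),
                     ["mirna_id", "gene_id"]].iloc[0]
        raise ValidationError(
            f"duplicate evidence pair ({dup['mirna_id']}, {dup['gene_id']})")
    if not ev["validated"].isin([0, 1]).all():
        raise ValidationError("validated must be 0 or 1")
    tc = ev["tool_count"]
    if ((tc < 0) | (tc > MAX_TOOL_COUNT)).any():
        raise ValidationError(f"tool_count outside [0, {MAX_TOOL_COUNT}]")
    ev = ev.copy()
    ev["validated"] = ev["validated"].astype(int)
    ev["tool_count"] = ev["tool_count"].astype(int)
    return ev


def write_evidence(ev: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    ev.to_csv(path, sep=sep, index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional universe restricting them."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if self.universe is not None and not genes <= self.universe:
                raise ValidationError(f"gene set {name!r} not contained in universe")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one gene")
            name, desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes_in = set(g for g in genes if g)
            if universe is not None:
                genes_in &= universe
            if not genes_in:
                raise ValidationError(f"{path}:{lineno}: set {name!r} empty"
                                      " (after universe restriction)")
            sets[name] = genes_in
            descriptions[name] = desc
    logger.info("read_gmt: %d sets from %s", len(sets), path)
    return GeneSetCollection(sets=sets, descriptions=descriptions, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(results, path: str | Path, format: str = "json") -> None:
    """Serialize a results object (dict / list of dicts / DataFrame)."""
    path = Path(path)
    if format == "json":
        if isinstance(results, pd.DataFrame):
            results = results.to_dict(orient="records")
        path.write_text(json.dumps(results, indent=2, default=_json_default) + "\n")
    elif format == "tsv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
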