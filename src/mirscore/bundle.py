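"""Domain types and readers/writers for every table the engine consumes or emits.

All matrices are stored sparse-by-cell in long-format TSV so fixtures stay
human-readable: a cell that is absent from the file was not measured and is
excluded from both numerator and denominator of the partial scores.  A
bundle directory holds::

    ectopic.tsv        dataset_id  mirna  gene  fold_change   (linear scale, > 0)
    knockout.tsv       dataset_id  mirna  gene  fold_change
    correlations.tsv   cancer_type mirna  gene  r             (Pearson, |r| <= 1)
    predictions.tsv    algorithm   mirna  gene                (positive calls only)
    algorithms.txt     one algorithm name per line (the scoring denominator)
    mirnas.txt         one mature miRNA name per line (optional; inferred if absent)
    genes.txt          one gene symbol per line (optional; inferred if absent)
    datasets.tsv       dataset_id  provenance                  (optional sidecar)

Identifiers are case-insensitive: gene symbols are upper-cased and miRNA
names lower-cased on load, which is idempotent and deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger(__name__)

ECTOPIC = "ectopic"
KNOCKOUT = "knockout_knockdown"


class FormatError(ValueError):
    """A file does not follow the expected tabular layout."""


class ValidationError(ValueError):
    """Loaded data violates a domain invariant."""


# ---------------------------------------------------------------------------
# identifier normalization


def normalize_gene(symbol: str) -> str:
    """Canonical (upper-case) form of a gene symbol; idempotent."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValidationError("empty gene symbol")
    return s


def normalize_mirna(name: str) -> str:
    """Canonical (lower-case) form of a mature miRNA name; idempotent."""
    s = str(name).strip().lower()
    if not s:
        raise ValidationError("empty miRNA name")
    return s


def _check_no_duplicates(ids: Iterable[str], what: str) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier after normalization: {i!r}")
        seen.add(i)
        out.append(i)
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FoldChangeDataset:
    """One ectopic-expression or knockout/knockdown mRNA profiling dataset.

    ``fold_change`` maps gene symbol to linear-scale treated/control ratio;
    genes the platform did not measure are simply absent.
    """

    dataset_id: str
    mirna: str
    intervention: str  # ECTOPIC or KNOCKOUT
    fold_change: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.intervention not in (ECTOPIC, KNOCKOUT):
            raise ValidationError(
                f"dataset {self.dataset_id}: unknown intervention {self.intervention!r}"
            )
        for gene, fc in self.fold_change.items():
            if not np.isfinite(fc) or fc <= 0:
                raise ValidationError(
                    f"dataset {self.dataset_id}, gene {gene}: fold change must be a "
                    f"positive real on the linear scale (got {fc!r})"
                )


@dataclass
class CorrelationPanel:
    """Per-cancer-type Pearson correlations between miRNA and mRNA expression."""

    cancer_type: str
    r: dict[tuple[str, str], float]  # (mirna, gene) -> coefficient; missing allowed

    def __post_init__(self) -> None:
        for (mirna, gene), val in self.r.items():
            if not np.isfinite(val) or abs(val) > 1.0:
                raise ValidationError(
                    f"correlation panel {self.cancer_type}, pair ({mirna}, {gene}): "
                    f"|r| must be <= 1 (got {val!r})"
                )


@dataclass
class PredictionCalls:
    """Binary target calls from a fixed complement of prediction algorithms.

    Only positive calls are stored; the scoring denominator is the size of
    ``algorithms`` (the configured complement), never the number of calls.
    """

    algorithms: list[str]
    calls: set[tuple[str, str, str]] = field(default_factory=set)  # (algorithm, mirna, gene)

    def __post_init__(self) -> None:
        self.algorithms = _check_no_duplicates(
            [str(a).strip() for a in self.algorithms], "algorithm"
        )
        known = set(self.algorithms)
        for alg, mirna, gene in self.calls:
            if alg not in known:
                raise ValidationError(
                    f"prediction call by {alg!r} for ({mirna}, {gene}) is outside "
                    f"the configured algorithm complement"
                )

    def positives(self, mirna: str, gene: str) -> int:
        return sum(1 for alg in self.algorithms if (alg, mirna, gene) in self.calls)


@dataclass
class ValidatedTargetCatalog:
    """Experimentally validated miRNA-target records (miRNA, gene, PMID, assay)."""

    records: pd.DataFrame  # columns: mirna, gene, pmid, assay

    REQUIRED = ("mirna", "gene", "pmid", "assay")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"validated-target catalog lacks columns {missing}")
        dup = self.records.duplicated(subset=["mirna", "gene", "pmid"])
        if dup.any():
            raise ValidationError(
                f"{int(dup.sum())} duplicate (miRNA, gene, PMID) records in catalog"
            )

    def targets_of(self, mirna: str, assay: str | None = None) -> set[str]:
        rec = self.records[self.records["mirna"] == mirna]
        if assay is not None:
            rec = rec[rec["assay"] == assay]
        return set(rec["gene"])


@dataclass
class EvidenceBundle:
    """All four evidence categories over one miRNA x gene universe."""

    ectopic: list[FoldChangeDataset]
    knockout: list[FoldChangeDataset]
    correlations: list[CorrelationPanel]
    predictions: PredictionCalls
    gene_universe: set[str]
    mirna_universe: set[str]

    # -- long-format views used by the vectorized scorer -------------------

    def fold_change_frame(self, intervention: str) -> pd.DataFrame:
        datasets = self.ectopic if intervention == ECTOPIC else self.knockout
        rows = []
        for ds in datasets:
            for gene, fc in ds.fold_change.items():
                rows.append((ds.dataset_id, ds.mirna, gene, fc))
        return pd.DataFrame(rows, columns=["dataset_id", "mirna", "gene", "fold_change"])

    def correlation_frame(self) -> pd.DataFrame:
        rows = []
        for panel in self.correlations:
            for (mirna, gene), val in panel.r.items():
                rows.append((panel.cancer_type, mirna, gene, val))
        return pd.DataFrame(rows, columns=["cancer_type", "mirna", "gene", "r"])

    def prediction_frame(self) -> pd.DataFrame:
        rows = list(self.predictions.calls)
        return pd.DataFrame(rows, columns=["algorithm", "mirna", "gene"])

    # -- per-pair accessors (detail reports) -------------------------------

    def ectopic_for(self, mirna: str, gene: str) -> dict[str, float]:
        return {
            ds.dataset_id: ds.fold_change[gene]
            for ds in self.ectopic
            if ds.mirna == mirna and gene in ds.fold_change
        }

    def knockout_for(self, mirna: str, gene: str) -> dict[str, float]:
        return {
            ds.dataset_id: ds.fold_change[gene]
            for ds in self.knockout
            if ds.mirna == mirna and gene in ds.fold_change
        }

    def correlations_for(self, mirna: str, gene: str) -> dict[str, float]:
        out = {}
        for panel in self.correlations:
            if (mirna, gene) in panel.r:
                out[panel.cancer_type] = panel.r[(mirna, gene)]
        return out

    def prediction_calls_for(self, mirna: str, gene: str) -> dict[str, bool]:
        return {
            alg: (alg, mirna, gene) in self.predictions.calls
            for alg in self.predictions.algorithms
        }


@dataclass
class ValidationReport:
    """Summary of a bundle's coverage; informational, never raises."""

    n_mirnas: int
    n_genes: int
    datasets_per_mirna: pd.DataFrame  # mirna x {ectopic, knockout, correlation_panels}
    mean_ectopic_per_mirna: float
    mean_knockout_per_mirna: float
    unscorable_genes: list[str]
    unscorable_mirnas: list[str]
    missing_cell_fraction: dict[str, float]
    warnings: list[str]

    @property
    def clean(self) -> bool:
        return not self.warnings


# ---------------------------------------------------------------------------
# loading


def _read_long_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}, line 1: header lacks required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    try:
        return df[col].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in column {col!r} ({exc})") from exc


def _load_fold_changes(
    path: Path, intervention: str, provenance: Mapping[str, str]
) -> list[FoldChangeDataset]:
    df = _read_long_tsv(path, ("dataset_id", "mirna", "gene", "fold_change"))
    if df.empty:
        return []
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].map(normalize_gene)
    df["fold_change"] = _to_float(df, "fold_change", path)
    bad = df[(~np.isfinite(df["fold_change"])) | (df["fold_change"] <= 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: dataset {row.dataset_id}, gene {row.gene}: fold change must "
            f"be positive (got {row.fold_change})"
        )
    dup = df.duplicated(subset=["dataset_id", "gene"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: dataset {row.dataset_id} lists gene {row.gene} more than once"
        )
    datasets = []
    for ds_id, sub in df.groupby("dataset_id", sort=True):
        mirnas = sub["mirna"].unique()
        if len(mirnas) != 1:
            raise ValidationError(
                f"{path}: dataset {ds_id} references {len(mirnas)} miRNAs "
                f"({sorted(mirnas)}); every dataset must reference exactly one"
            )
        datasets.append(
            FoldChangeDataset(
                dataset_id=str(ds_id),
                mirna=mirnas[0],
                intervention=intervention,
                fold_change=dict(zip(sub["gene"], sub["fold_change"])),
                provenance=provenance.get(str(ds_id), ""),
            )
        )
    return datasets


def _load_correlations(path: Path) -> list[CorrelationPanel]:
    df = _read_long_tsv(path, ("cancer_type", "mirna", "gene", "r"))
    if df.empty:
        return []
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].map(normalize_gene)
    df["r"] = _to_float(df, "r", path)
    bad = df[(~np.isfinite(df["r"])) | (df["r"].abs() > 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"{path}: panel {row.cancer_type}, pair ({row.mirna}, {row.gene}): "
            f"|r| must be <= 1 (got {row.r})"
        )
    dup = df.duplicated(subset=["cancer_type", "mirna", "gene"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: panel {row.cancer_type} lists pair ({row.mirna}, {row.gene}) "
            f"more than once"
        )
    panels = []
    for entity, sub in df.groupby("cancer_type", sort=True):
        panels.append(
            CorrelationPanel(
                cancer_type=str(entity),
                r=dict(zip(zip(sub["mirna"], sub["gene"]), sub["r"])),
            )
        )
    return panels


def _load_predictions(path: Path, algorithms: list[str]) -> PredictionCalls:
    df = _read_long_tsv(path, ("algorithm", "mirna", "gene"))
    if df.empty:
        return PredictionCalls(algorithms=algorithms)
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].map(normalize_gene)
    df["algorithm"] = df["algorithm"].str.strip()
    calls = set(zip(df["algorithm"], df["mirna"], df["gene"]))
    return PredictionCalls(algorithms=algorithms, calls=calls)


def _read_id_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; normalized, order kept."""
    return _check_no_duplicates(
        [normalize_gene(s) for s in _read_id_list(Path(path))], "gene"
    )


def load_bundle(bundle_dir: str | Path, config: RunConfig | None = None) -> EvidenceBundle:
    """Load and validate an evidence bundle from a directory of long-format TSVs.

    Missing experimental files (``ectopic.tsv``, ``knockout.tsv``,
    ``correlations.tsv``) yield empty categories with a warning;
    ``predictions.tsv`` and ``algorithms.txt`` are required because the
    prediction category anchors the composite score.
    """
    d = Path(bundle_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {d}")

    provenance: dict[str, str] = {}
    ds_meta = d / "datasets.tsv"
    if ds_meta.exists():
        meta = _read_long_tsv(ds_meta, ("dataset_id", "provenance"))
        provenance = dict(zip(meta["dataset_id"], meta["provenance"].fillna("")))

    ectopic: list[FoldChangeDataset] = []
    knockout: list[FoldChangeDataset] = []
    correlations: list[CorrelationPanel] = []
    if (d / "ectopic.tsv").exists():
        ectopic = _load_fold_changes(d / "ectopic.tsv", ECTOPIC, provenance)
    else:
        warnings.warn(f"{d}: no ectopic.tsv; ectopic category empty", stacklevel=2)
    if (d / "knockout.tsv").exists():
        knockout = _load_fold_changes(d / "knockout.tsv", KNOCKOUT, provenance)
    else:
        warnings.warn(f"{d}: no knockout.tsv; knockout category empty", stacklevel=2)
    if (d / "correlations.tsv").exists():
        correlations = _load_correlations(d / "correlations.tsv")
    else:
        warnings.warn(f"{d}: no correlations.tsv; correlation category empty", stacklevel=2)

    alg_path = d / "algorithms.txt"
    if not alg_path.exists():
        raise FileNotFoundError(
            f"{d}: algorithms.txt (the prediction-algorithm complement) is required"
        )
    algorithms = _read_id_list(alg_path)
    if not algorithms:
        raise ValidationError(f"{alg_path}: algorithm complement is empty")
    pred_path = d / "predictions.tsv"
    if not pred_path.exists():
        raise FileNotFoundError(f"{d}: predictions.tsv is required")
    predictions = _load_predictions(pred_path, algorithms)

    seen_mirnas: set[str] = set()
    seen_genes: set[str] = set()
    for ds in ectopic + knockout:
        seen_mirnas.add(ds.mirna)
        seen_genes.update(ds.fold_change)
    for panel in correlations:
        for mirna, gene in panel.r:
            seen_mirnas.add(mirna)
            seen_genes.add(gene)
    for _, mirna, gene in predictions.calls:
        seen_mirnas.add(mirna)
        seen_genes.add(gene)

    if (d / "mirnas.txt").exists():
        mirna_universe = set(
            _check_no_duplicates(
                [normalize_mirna(m) for m in _read_id_list(d / "mirnas.txt")], "miRNA"
            )
        )
    else:
        mirna_universe = set(seen_mirnas)
    if (d / "genes.txt").exists():
        gene_universe = set(read_gene_list(d / "genes.txt"))
    else:
        gene_universe = set(seen_genes)

    stray_m = seen_mirnas - mirna_universe
    stray_g = seen_genes - gene_universe
    if stray_m:
        raise ValidationError(
            f"{d}: miRNA identifiers outside the declared universe: {sorted(stray_m)[:5]}"
        )
    if stray_g:
        raise ValidationError(
            f"{d}: gene identifiers outside the declared universe: {sorted(stray_g)[:5]}"
        )

    bundle = EvidenceBundle(
        ectopic=ectopic,
        knockout=knockout,
        correlations=correlations,
        predictions=predictions,
        gene_universe=gene_universe,
        mirna_universe=mirna_universe,
    )
    logger.info(
        "loaded bundle from %s: %d ectopic, %d knockout datasets, %d correlation "
        "panels, %d algorithms, %d miRNAs, %d genes",
        d, len(ectopic), len(knockout), len(correlations),
        len(algorithms), len(mirna_universe), len(gene_universe),
    )
    return bundle


# ---------------------------------------------------------------------------
# validation report


def validate_bundle(bundle: EvidenceBundle) -> ValidationReport:
    """Coverage report: datasets per miRNA, orphan identifiers, missing cells."""
    warns: list[str] = []
    mirnas = sorted(bundle.mirna_universe)
    genes = sorted(bundle.gene_universe)

    ec_counts = pd.Series(0, index=mirnas, dtype=int)
    ko_counts = pd.Series(0, index=mirnas, dtype=int)
    for ds in bundle.ectopic:
        ec_counts[ds.mirna] += 1
    for ds in bundle.knockout:
        ko_counts[ds.mirna] += 1
    corr_counts = pd.Series(0, index=mirnas, dtype=int)
    panel_mirnas: dict[str, set[str]] = {}
    for panel in bundle.correlations:
        ms = {m for m, _ in panel.r}
        panel_mirnas[panel.cancer_type] = ms
        for m in ms & set(mirnas):
            corr_counts[m] += 1

    per_mirna = pd.DataFrame(
        {"ectopic": ec_counts, "knockout": ko_counts, "correlation_panels": corr_counts}
    )

    covered_m = ec_counts[ec_counts > 0].index.union(ko_counts[ko_counts > 0].index)
    covered_m = covered_m.union(corr_counts[corr_counts > 0].index)
    pred_m = {m for _, m, _ in bundle.predictions.calls}
    covered_m = set(covered_m) | pred_m
    unscorable_mirnas = sorted(set(mirnas) - covered_m)

    covered_g: set[str] = set()
    for ds in bundle.ectopic + bundle.knockout:
        covered_g.update(ds.fold_change)
    for panel in bundle.correlations:
        covered_g.update(g for _, g in panel.r)
    covered_g.update(g for _, _, g in bundle.predictions.calls)
    unscorable_genes = sorted(set(genes) - covered_g)

    def _missing_frac(n_present: int, n_possible: int) -> float:
        return 1.0 - n_present / n_possible if n_possible else 0.0

    n_g = len(genes)
    missing = {}
    n_fc_cells = sum(len(ds.fold_change) for ds in bundle.ectopic)
    missing["ectopic"] = _missing_frac(n_fc_cells, len(bundle.ectopic) * n_g)
    n_ko_cells = sum(len(ds.fold_change) for ds in bundle.knockout)
    missing["knockout"] = _missing_frac(n_ko_cells, len(bundle.knockout) * n_g)
    n_corr_cells = sum(len(p.r) for p in bundle.correlations)
    missing["correlation"] = _missing_frac(
        n_corr_cells, len(bundle.correlations) * n_g * len(mirnas)
    )

    if unscorable_mirnas:
        warns.append(
            f"{len(unscorable_mirnas)} miRNA(s) have no evidence in any category "
            f"(e.g. {unscorable_mirnas[:3]})"
        )
    if unscorable_genes:
        warns.append(
            f"{len(unscorable_genes)} gene(s) appear in no category and are "
            f"unscorable (e.g. {unscorable_genes[:3]})"
        )
    for cat, frac in missing.items():
        if frac > 0.5:
            warns.append(f"{cat}: {frac:.0%} of cells missing")

    scored = ec_counts[ec_counts > 0]
    mean_ec = float(scored.mean()) if len(scored) else 0.0
    scored_ko = ko_counts[ko_counts > 0]
    mean_ko = float(scored_ko.mean()) if len(scored_ko) else 0.0

    return ValidationReport(
        n_mirnas=len(mirnas),
        n_genes=len(genes),
        datasets_per_mirna=per_mirna,
        mean_ectopic_per_mirna=mean_ec,
        mean_knockout_per_mirna=mean_ko,
        unscorable_genes=unscorable_genes,
        unscorable_mirnas=unscorable_mirnas,
        missing_cell_fraction=missing,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# score-table IO


SCORE_COLUMNS = [
    "mirna", "gene",
    "score_ectopic", "n_ectopic_support", "n_ectopic_total",
    "score_knockout", "n_knockout_support", "n_knockout_total",
    "score_correlation", "n_correlation_support", "n_correlation_total",
    "score_prediction", "n_prediction_support", "n_prediction_total",
    "composite", "mirna_rank", "mrna_rank", "categories",
]


def write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a TSV with optional '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_score_table(table, path: str | Path, config: RunConfig | None = None) -> None:
    """Serialize a score table to TSV (one row per scored miRNA-gene pair)."""
    from .scoring import ScoreTable  # local import to avoid a cycle

    df = table.frame if isinstance(table, ScoreTable) else table
    header = []
    if config is not None:
        header.append(f"config: {config.to_json()}")
    write_tsv(df[SCORE_COLUMNS], path, header)


def read_score_table(path: str | Path):
    """Read a score table written by :func:`write_score_table`."""
    from .scoring import ScoreTable

    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"mirna": str, "gene": str, "categories": str},
    )
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: score table lacks columns {missing}")
    int_cols = [c for c in df.columns if c.startswith("n_") or c.endswith("_rank")]
    for c in int_cols:
        df[c] = df[c].astype(int)
    return ScoreTable(df)


def read_validated_catalog(path: str | Path) -> ValidatedTargetCatalog:
    """Read a validated-target catalog TSV (mirna, gene, pmid, assay)."""
    df = _read_long_tsv(Path(path), ("mirna", "gene", "pmid", "assay"))
    df["mirna"] = df["mirna"].map(normalize_mirna)
    df["gene"] = df["gene"].map(normalize_gene)
    df["assay"] = df["assay"].str.strip()
    return ValidatedTargetCatalog(records=df)
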