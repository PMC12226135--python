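"""Candidate queries over the score table and clinical annotations.

Two query directions share one criteria object: the targets of a miRNA
(candidates are genes) and the miRNA regulators of an mRNA (candidates
are miRNAs).  Active criteria compose as set intersection -- a candidate
survives only if it passes every one -- and are evaluated either in a
single cancer type or as "significant in at least X % of cancer types",
where the denominator counts the entities in which the candidate has an
evaluable (determined) record for that criterion.

The detail report assembles every piece of raw evidence and annotation
behind one miRNA-gene pair into a single JSON-serialisable document.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import EvidenceBundle
from .clinical import Annotations, DOWN, GOOD, POOR, UP
from .scoring import ScoreTable

TARGETS_OF_MIRNA = "targets_of_mirna"
REGULATORS_OF_MRNA = "regulators_of_mrna"


@dataclass
class QueryCriteria:
    """Filter settings for a candidate query.

    ``entity`` restricts evaluation to one cancer type; otherwise
    ``min_fraction`` requires each active criterion to hold in at least
    that fraction (inclusive) of the entities with evaluable data for the
    candidate.  ``max_rank`` cuts on the query-axis rank and
    ``min_score`` on the composite score.
    """

    direction: str = TARGETS_OF_MIRNA
    survival_filter: str | None = None     # POOR or GOOD
    de_filter: str | None = None           # UP or DOWN
    dependency_required: bool = False
    druggable_required: bool = False
    entity: str | None = None
    min_fraction: float | None = None
    max_rank: int | None = None
    min_score: float | None = None
    dependency_mode: str = "either"        # "either" or "both" screens

    def __post_init__(self) -> None:
        if self.direction not in (TARGETS_OF_MIRNA, REGULATORS_OF_MRNA):
            raise ValueError(f"unknown query direction {self.direction!r}")
        if self.survival_filter not in (None, POOR, GOOD):
            raise ValueError(f"unknown survival filter {self.survival_filter!r}")
        if self.de_filter not in (None, UP, DOWN):
            raise ValueError(f"unknown DE filter {self.de_filter!r}")
        if self.min_fraction is not None and not (0.0 < self.min_fraction <= 1.0):
            raise ValueError(f"min_fraction must lie in (0, 1] (got {self.min_fraction})")
        if self.entity is not None and self.min_fraction is not None:
            raise ValueError("give either a single entity or min_fraction, not both")
        if self.dependency_mode not in ("either", "both"):
            raise ValueError(f"unknown dependency mode {self.dependency_mode!r}")


def oncogenic_target_preset(**kwargs) -> QueryCriteria:
    """Convenience preset: up-in-tumour, poor-survival targets of a miRNA."""
    return QueryCriteria(survival_filter=POOR, de_filter=UP, **kwargs)


def tumor_suppressive_target_preset(**kwargs) -> QueryCriteria:
    """Mirror preset: down-in-tumour, good-survival targets."""
    return QueryCriteria(survival_filter=GOOD, de_filter=DOWN, **kwargs)


def _direction_counts(
    table: pd.DataFrame, feature: str, wanted: str, entity: str | None
) -> tuple[int, int]:
    """(matching entities, evaluable entities) for one feature and direction."""
    sub = table[table["feature"] == feature]
    if entity is not None:
        sub = sub[sub["entity"] == entity]
    evaluable = sub[~sub["undetermined"].astype(bool)]
    n_eval = len(evaluable)
    n_match = int((evaluable["direction"] == wanted).sum())
    return n_match, n_eval


def _dependency_counts(
    dep: pd.DataFrame, gene: str, entity: str | None, mode: str
) -> tuple[int, int]:
    sub = dep[dep["gene"] == gene]
    if entity is not None:
        sub = sub[sub["entity"] == entity]
    if sub.empty:
        return 0, 0
    agg = sub.groupby("entity")["dependent"].agg(["any", "all", "count"])
    n_eval = len(agg)
    flag = agg["any"] if mode == "either" else agg["all"]
    return int(flag.sum()), n_eval


def _passes(n_match: int, n_eval: int, criteria: QueryCriteria) -> bool:
    if n_eval == 0:
        return False
    if criteria.entity is not None or criteria.min_fraction is None:
        return n_match >= 1
    return n_match / n_eval >= criteria.min_fraction


def filter_candidates(
    score_table: ScoreTable,
    annotations: Annotations,
    query_id: str,
    criteria: QueryCriteria,
) -> pd.DataFrame:
    """Ranked candidates for a query, filtered by every active criterion.

    ``query_id`` is the miRNA (targets query) or the gene (regulators
    query).  Clinical criteria are evaluated on the candidate feature.
    Empty results are valid (criteria may be contradictory); an unknown
    entity raises a lookup error.
    """
    if criteria.entity is not None:
        known = set(annotations.de["entity"]) | set(annotations.survival["entity"]) | (
            set(annotations.dependency["entity"]) if len(annotations.dependency) else set()
        )
        if criteria.entity not in known:
            raise LookupError(f"unknown cancer entity {criteria.entity!r}")

    if criteria.direction == TARGETS_OF_MIRNA:
        cands = score_table.targets_of(query_id).copy()
        cand_col, rank_col = "gene", "mirna_rank"
    else:
        cands = score_table.regulators_of(query_id).copy()
        cand_col, rank_col = "mirna", "mrna_rank"

    if criteria.max_rank is not None:
        cands = cands[cands[rank_col] <= criteria.max_rank]
    if criteria.min_score is not None:
        cands = cands[cands["composite"] >= criteria.min_score]

    keep_rows = []
    for _, row in cands.iterrows():
        feature = row[cand_col]
        info: dict[str, object] = {}
        ok = True
        if criteria.de_filter is not None:
            n_match, n_eval = _direction_counts(
                annotations.de, feature, criteria.de_filter, criteria.entity
            )
            ok &= _passes(n_match, n_eval, criteria)
            info["de_pass"] = f"{n_match}/{n_eval}"
        if criteria.survival_filter is not None:
            n_match, n_eval = _direction_counts(
                annotations.survival, feature, criteria.survival_filter, criteria.entity
            )
            ok &= _passes(n_match, n_eval, criteria)
            info["survival_pass"] = f"{n_match}/{n_eval}"
        if criteria.dependency_required:
            n_match, n_eval = _dependency_counts(
                annotations.dependency, feature, criteria.entity, criteria.dependency_mode
            )
            ok &= _passes(n_match, n_eval, criteria)
            info["dependency_pass"] = f"{n_match}/{n_eval}"
        if criteria.druggable_required:
            is_drug = feature in annotations.druggable
            ok &= is_drug
            info["druggable"] = bool(is_drug)
        if ok:
            keep_rows.append({**row.to_dict(), **info})

    out = pd.DataFrame(keep_rows)
    if out.empty:
        cols = list(cands.columns)
        return pd.DataFrame(columns=cols)
    return out.sort_values(
        ["composite", cand_col], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# detail report


def _nearest(identifier: str, pool: list[str]) -> list[str]:
    return difflib.get_close_matches(identifier, pool, n=3, cutoff=0.4)


def _records(df: pd.DataFrame, feature: str) -> list[dict]:
    sub = df[df["feature"] == feature]
    recs = sub.drop(columns=["feature"]).to_dict(orient="records")
    return [
        {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in r.items()}
        for r in recs
    ]


def detail_report(
    mirna: str,
    gene: str,
    bundle: EvidenceBundle,
    score_table: ScoreTable,
    annotations: Annotations,
) -> dict:
    """Structured per-pair report: scores, raw evidence and all annotations.

    Sections mirror what a reviewer wants to see at a glance: the
    composite score with both ranks, per-algorithm prediction calls,
    per-dataset ectopic and knockout fold changes, per-entity
    correlations, both features' differential expression and survival
    associations, and the gene's dependency calls.  Raises a lookup error
    naming the nearest identifiers when the pair is not scored.
    """
    try:
        row = score_table.pair(mirna, gene)
    except LookupError:
        hints = []
        if mirna not in set(score_table.frame["mirna"]):
            hints.append(f"miRNA {mirna!r}; nearest: {_nearest(mirna, score_table.mirnas)}")
        if gene not in set(score_table.frame["gene"]):
            hints.append(f"gene {gene!r}; nearest: {_nearest(gene, score_table.genes)}")
        detail = "; ".join(hints) if hints else "pair carries no evidence"
        raise LookupError(f"pair ({mirna}, {gene}) not scored -- {detail}") from None

    def fc_section(values: dict[str, float]) -> dict | str:
        return values if values else "no data"

    dep = annotations.dependency
    dep_sub = dep[dep["gene"] == gene] if len(dep) else dep
    report = {
        "pair": {"mirna": mirna, "gene": gene},
        "score": {
            "composite": float(row["composite"]),
            "mirna_rank": int(row["mirna_rank"]),
            "mrna_rank": int(row["mrna_rank"]),
            "partials": {
                "ectopic": None if pd.isna(row["score_ectopic"]) else float(row["score_ectopic"]),
                "knockout": None if pd.isna(row["score_knockout"]) else float(row["score_knockout"]),
                "correlation": None if pd.isna(row["score_correlation"]) else float(row["score_correlation"]),
                "prediction": float(row["score_prediction"]),
            },
            "categories": str(row["categories"]),
        },
        "prediction_calls": bundle.prediction_calls_for(mirna, gene),
        "ectopic_fold_changes": fc_section(bundle.ectopic_for(mirna, gene)),
        "knockout_fold_changes": fc_section(bundle.knockout_for(mirna, gene)),
        "correlations": fc_section(bundle.correlations_for(mirna, gene)),
        "mirna_differential_expression": _records(annotations.de, mirna),
        "gene_differential_expression": _records(annotations.de, gene),
        "mirna_survival": _records(annotations.survival, mirna),
        "gene_survival": _records(annotations.survival, gene),
        "gene_dependency": dep_sub.to_dict(orient="records") if len(dep_sub) else "no data",
        "gene_druggable": gene in annotations.druggable,
    }
    return report
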