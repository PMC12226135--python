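"""Per-miRNA clinical summary scores over the top-ranked target set.

For every miRNA the top-k targets by composite score (k = 1000 by
default) are extracted and, per cancer type, each target contributes
+1 / -1 / 0 to two sums:

* tumour/normal target score: +1 when the target is significantly
  up-regulated in tumours, -1 when down-regulated;
* overall-survival target score: +1 when high expression of the target
  is significantly associated with poor survival, -1 with good survival.

A strongly positive tumour/normal score therefore means the miRNA's
predicted targets behave like oncogenes (up in tumours), the pattern
expected for targets of a tumour-suppressive miRNA.  Targets without an
evaluable record in an entity contribute 0, keeping scores comparable
across miRNAs because the sum always runs over a fixed-size top set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .clinical import Annotations, DOWN, GOOD, POOR, UP
from .scoring import ScoreTable

TUMOR_NORMAL = "tumor_normal"
OVERALL_SURVIVAL = "overall_survival"


@dataclass
class TargetSummaryScore:
    mirna: str
    entity: str
    kind: str  # TUMOR_NORMAL or OVERALL_SURVIVAL
    score: int
    n_plus: int   # up_in_tumor resp. poor_with_high
    n_minus: int  # down_in_tumor resp. good_with_high
    top_set_size: int


def extract_top_targets(score_table: ScoreTable, mirna: str, k: int = 1000) -> list[str]:
    """The miRNA's top-k target genes ordered by rank (1 = best).

    Returns all scored genes (with a warning) when fewer than ``k`` are
    available.
    """
    targets = score_table.targets_of(mirna)  # raises LookupError when unknown
    genes = targets.sort_values("mirna_rank")["gene"].tolist()
    if len(genes) < k:
        warnings.warn(
            f"{mirna}: only {len(genes)} scored targets available (requested top {k})",
            stacklevel=2,
        )
        return genes
    return genes[:k]


def _signed_sum(
    top_set: list[str],
    table: pd.DataFrame,
    plus_label: str,
    minus_label: str,
) -> tuple[int, int, int]:
    directions = table.set_index("feature")["direction"]
    directions = directions[~directions.index.duplicated()]
    n_plus = n_minus = 0
    for gene in top_set:
        d = directions.get(gene)
        if d == plus_label:
            n_plus += 1
        elif d == minus_label:
            n_minus += 1
    return n_plus - n_minus, n_plus, n_minus


def tumor_normal_target_score(
    top_set: list[str], annotations: Annotations, entity: str, mirna: str = ""
) -> TargetSummaryScore:
    """Signed sum of significant tumour-vs-normal directions over the top set."""
    de = annotations.de_for(entity)  # raises LookupError when entity absent
    score, n_up, n_down = _signed_sum(top_set, de, UP, DOWN)
    return TargetSummaryScore(
        mirna=mirna, entity=entity, kind=TUMOR_NORMAL,
        score=score, n_plus=n_up, n_minus=n_down, top_set_size=len(top_set),
    )


def overall_survival_target_score(
    top_set: list[str], annotations: Annotations, entity: str, mirna: str = ""
) -> TargetSummaryScore:
    """Signed sum of significant survival directions over the top set."""
    surv = annotations.survival_for(entity)
    score, n_poor, n_good = _signed_sum(top_set, surv, POOR, GOOD)
    return TargetSummaryScore(
        mirna=mirna, entity=entity, kind=OVERALL_SURVIVAL,
        score=score, n_plus=n_poor, n_minus=n_good, top_set_size=len(top_set),
    )


def compute_target_summary(
    score_table: ScoreTable,
    annotations: Annotations,
    k: int = 1000,
) -> pd.DataFrame:
    """Both summary scores for every miRNA x entity with available annotation.

    Also attaches the miRNA's own differential-expression and survival
    direction in the entity (its class in tumour-suppressive vs
    oncogenic terms), so consumers can group miRNAs the way the summary
    heat maps do.
    """
    rows = []
    for mirna in score_table.mirnas:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = extract_top_targets(score_table, mirna, k)
        for entity in annotations.de_entities:
            s = tumor_normal_target_score(top, annotations, entity, mirna)
            de = annotations.de_for(entity)
            own = de[de["feature"] == mirna]
            rows.append(
                {
                    "mirna": mirna, "entity": entity, "kind": s.kind,
                    "score": s.score, "n_plus": s.n_plus, "n_minus": s.n_minus,
                    "top_set_size": s.top_set_size,
                    "mirna_direction": own["direction"].iloc[0] if len(own) else "na",
                }
            )
        for entity in annotations.survival_entities:
            s = overall_survival_target_score(top, annotations, entity, mirna)
            sv = annotations.survival_for(entity)
            own = sv[sv["feature"] == mirna]
            rows.append(
                {
                    "mirna": mirna, "entity": entity, "kind": s.kind,
                    "score": s.score, "n_plus": s.n_plus, "n_minus": s.n_minus,
                    "top_set_size": s.top_set_size,
                    "mirna_direction": own["direction"].iloc[0] if len(own) else "na",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna", "entity", "kind", "score", "n_plus", "n_minus",
                 "top_set_size", "mirna_direction"],
    )
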