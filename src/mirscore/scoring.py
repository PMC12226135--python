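"""Partial evidence scores, the composite target-prediction score, and ranks.

Each evidence category contributes a partial score: the percentage of its
datasets that support the miRNA-mRNA pair under a strict threshold ---
repression (fold change < 0.8) in ectopic-miRNA datasets, induction
(fold change > 1.25) in knockout/knockdown datasets, anti-correlation
(Pearson r < -0.1) across cancer types, and the fraction of prediction
algorithms calling the pair a target.  The composite score is the equally
weighted mean of the partial scores of the categories that have data, so
its ceiling is 100: with all four categories present it is the sum of the
four partials divided by 4, and with only correlation and prediction data
available it reduces to their sum divided by 2.

A pair with no fold-change measurement, no correlation cell and no
positive prediction call carries no evidence at all and is omitted from
the table rather than scored 0, which keeps "no data" distinct from
"contradicting data".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bundle import ECTOPIC, EvidenceBundle, SCORE_COLUMNS, ValidationError
from .config import RunConfig

CATEGORY_LETTERS = {"ectopic": "E", "knockout": "K", "correlation": "C", "prediction": "P"}


class UnscorableError(ValueError):
    """Every evidence category is absent for the pair."""


@dataclass
class PartialScores:
    """Per-category partial scores with their supporting/total counts.

    A partial of ``None`` means the category has no data for the pair.
    The prediction partial is never ``None`` once any evidence exists:
    zero calls over the algorithm complement score 0, not absent.
    """

    ectopic: float | None = None
    knockout: float | None = None
    correlation: float | None = None
    prediction: float | None = None
    counts: dict[str, tuple[int, int]] | None = None

    def present(self) -> list[str]:
        return [
            name
            for name in ("ectopic", "knockout", "correlation", "prediction")
            if getattr(self, name) is not None
        ]

    def availability_mask(self) -> str:
        return "".join(CATEGORY_LETTERS[name] for name in self.present())


def _partial(values: Sequence[float], support: np.ndarray) -> float | None:
    n = len(values)
    if n == 0:
        return None
    return 100.0 * float(np.count_nonzero(support)) / n


def partial_ectopic(fold_changes: Sequence[float], threshold: float = 0.8) -> float | None:
    """Percentage of ectopic-miRNA datasets with fold change strictly below ``threshold``.

    Returns ``None`` when the category has no datasets for the pair.
    """
    fc = np.asarray(list(fold_changes), dtype=float)
    if fc.size and (not np.all(np.isfinite(fc)) or np.any(fc <= 0)):
        raise ValidationError("ectopic fold changes must be positive reals")
    return _partial(fc, fc < threshold)


def partial_knockout(fold_changes: Sequence[float], threshold: float = 1.25) -> float | None:
    """Percentage of knockout/knockdown datasets with fold change strictly above ``threshold``."""
    fc = np.asarray(list(fold_changes), dtype=float)
    if fc.size and (not np.all(np.isfinite(fc)) or np.any(fc <= 0)):
        raise ValidationError("knockout fold changes must be positive reals")
    return _partial(fc, fc > threshold)


def partial_correlation(rs: Sequence[float], threshold: float = -0.1) -> float | None:
    """Percentage of cancer types with Pearson r strictly below ``threshold``."""
    r = np.asarray(list(rs), dtype=float)
    if r.size and (not np.all(np.isfinite(r)) or np.any(np.abs(r) > 1)):
        raise ValidationError("correlation coefficients must satisfy |r| <= 1")
    return _partial(r, r < threshold)


def partial_prediction(calls: Iterable[bool], n_algorithms: int | None = None) -> float:
    """Percentage of the algorithm complement predicting the pair.

    The denominator is the configured complement size (default: the number
    of supplied calls), never the count of positive calls, so zero
    positives score 0 rather than absent.
    """
    calls = list(calls)
    n = len(calls) if n_algorithms is None else int(n_algorithms)
    if n < 1:
        raise ValidationError("prediction-algorithm complement must be non-empty")
    if len(calls) > n:
        raise ValidationError(
            f"{len(calls)} calls exceed the declared complement of {n} algorithms"
        )
    return 100.0 * sum(bool(c) for c in calls) / n


def composite_score(partials: PartialScores) -> float:
    """Equally weighted mean of the present partial scores (ceiling 100).

    With all four categories present this is the sum of partials divided
    by 4; when neither ectopic nor knockout data exist it reduces to the
    correlation+prediction sum divided by 2.
    """
    present = partials.present()
    if not present:
        raise UnscorableError("no evidence category present; pair is unscorable")
    vals = [getattr(partials, name) for name in present]
    return float(sum(vals)) / len(vals)


@dataclass
class ScoreTable:
    """Composite and partial scores with bidirectional ranks, one row per pair.

    ``mirna_rank`` orders the genes within one miRNA (1 = best target);
    ``mrna_rank`` orders the miRNAs within one gene (1 = best regulator).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("mirna", "gene", "composite") if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"score table lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.frame["mirna"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    def targets_of(self, mirna: str) -> pd.DataFrame:
        """All scored targets of a miRNA, best first."""
        sub = self.frame[self.frame["mirna"] == mirna]
        if sub.empty:
            raise LookupError(f"miRNA {mirna!r} not present in score table")
        return sub.sort_values("mirna_rank").reset_index(drop=True)

    def regulators_of(self, gene: str) -> pd.DataFrame:
        """All scored miRNA regulators of a gene, best first."""
        sub = self.frame[self.frame["gene"] == gene]
        if sub.empty:
            raise LookupError(f"gene {gene!r} not present in score table")
        return sub.sort_values("mrna_rank").reset_index(drop=True)

    def pair(self, mirna: str, gene: str) -> pd.Series:
        sub = self.frame[(self.frame["mirna"] == mirna) & (self.frame["gene"] == gene)]
        if sub.empty:
            raise LookupError(f"pair ({mirna}, {gene}) not scored")
        return sub.iloc[0]

    def ranked_list(self, mirna: str) -> pd.Series:
        """Descending composite scores of a miRNA's targets, tie-broken by gene id.

        This is the ranking that enrichment analyses consume.
        """
        sub = self.targets_of(mirna)
        sub = sub.sort_values(["composite", "gene"], ascending=[False, True])
        return pd.Series(sub["composite"].to_numpy(), index=sub["gene"].to_numpy())


def rank_bidirectional(frame: pd.DataFrame) -> pd.DataFrame:
    """Fill ``mirna_rank`` and ``mrna_rank`` (1 = best) from composite scores.

    Ranks are a bijection onto 1..N within each group; ties are broken by
    the lexicographically smaller identifier so the result is invariant to
    input row order.
    """
    df = frame.sort_values(["mirna", "gene"], kind="mergesort").reset_index(drop=True)
    df = df.sort_values(
        ["mirna", "composite", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    df["mirna_rank"] = df.groupby("mirna", sort=False).cumcount() + 1
    df = df.sort_values(
        ["gene", "composite", "mirna"], ascending=[True, False, True], kind="mergesort"
    )
    df["mrna_rank"] = df.groupby("gene", sort=False).cumcount() + 1
    return df.sort_values(["mirna", "mirna_rank"], kind="mergesort").reset_index(drop=True)


def _category_counts(
    long: pd.DataFrame, support: pd.Series, prefix: str
) -> pd.DataFrame:
    g = long.assign(_sup=support.astype(int)).groupby(["mirna", "gene"], sort=False)
    out = g["_sup"].agg(["sum", "count"])
    out.columns = [f"n_{prefix}_support", f"n_{prefix}_total"]
    return out


def compute_scores(bundle: EvidenceBundle, config: RunConfig | None = None) -> ScoreTable:
    """Score every miRNA-gene pair that carries at least one piece of evidence."""
    cfg = config or RunConfig()

    ec = bundle.fold_change_frame(ECTOPIC)
    ko = bundle.fold_change_frame("knockout_knockdown")
    corr = bundle.correlation_frame()
    pred = bundle.prediction_frame()
    n_alg = len(bundle.predictions.algorithms)
    if n_alg < 1:
        raise ValidationError("prediction-algorithm complement must be non-empty")

    pieces = []
    if not ec.empty:
        pieces.append(_category_counts(ec, ec["fold_change"] < cfg.fc_down, "ectopic"))
    if not ko.empty:
        pieces.append(_category_counts(ko, ko["fold_change"] > cfg.fc_up, "knockout"))
    if not corr.empty:
        pieces.append(_category_counts(corr, corr["r"] < cfg.r_cut, "correlation"))
    if not pred.empty:
        pc = pred.groupby(["mirna", "gene"], sort=False).size().to_frame("n_prediction_support")
        pieces.append(pc)
    if not pieces:
        raise UnscorableError("bundle carries no evidence in any category")

    df = pd.concat(pieces, axis=1, join="outer")
    for col in (
        "n_ectopic_support", "n_ectopic_total",
        "n_knockout_support", "n_knockout_total",
        "n_correlation_support", "n_correlation_total",
        "n_prediction_support",
    ):
        if col not in df.columns:
            df[col] = 0
    df = df.fillna(0).astype(int)
    df["n_prediction_total"] = n_alg

    def pct(sup: pd.Series, tot: pd.Series) -> pd.Series:
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * sup / tot.where(tot > 0)

    df["score_ectopic"] = pct(df["n_ectopic_support"], df["n_ectopic_total"])
    df["score_knockout"] = pct(df["n_knockout_support"], df["n_knockout_total"])
    df["score_correlation"] = pct(df["n_correlation_support"], df["n_correlation_total"])
    df["score_prediction"] = 100.0 * df["n_prediction_support"] / n_alg

    partial_cols = ["score_ectopic", "score_knockout", "score_correlation", "score_prediction"]
    present = pd.DataFrame(
        {
            "score_ectopic": df["n_ectopic_total"] > 0,
            "score_knockout": df["n_knockout_total"] > 0,
            "score_correlation": df["n_correlation_total"] > 0,
            "score_prediction": True,
        },
        index=df.index,
    )
    df["composite"] = df[partial_cols].where(present).mean(axis=1)
    letters = np.array(["E", "K", "C", "P"])
    df["categories"] = ["".join(letters[row]) for row in present.to_numpy()]

    df = df.reset_index()
    df = rank_bidirectional(df)
    return ScoreTable(df[SCORE_COLUMNS].copy())


def pair_scores(bundle: EvidenceBundle, mirna: str, gene: str,
                config: RunConfig | None = None) -> PartialScores:
    """Partial scores for one pair, straight from the bundle's raw evidence."""
    cfg = config or RunConfig()
    ec = list(bundle.ectopic_for(mirna, gene).values())
    ko = list(bundle.knockout_for(mirna, gene).values())
    rs = list(bundle.correlations_for(mirna, gene).values())
    calls = bundle.prediction_calls_for(mirna, gene)
    n_pos = sum(calls.values())
    has_any = bool(ec or ko or rs or n_pos)
    counts = {
        "ectopic": (int(np.sum(np.asarray(ec) < cfg.fc_down)) if ec else 0, len(ec)),
        "knockout": (int(np.sum(np.asarray(ko) > cfg.fc_up)) if ko else 0, len(ko)),
        "correlation": (int(np.sum(np.asarray(rs) < cfg.r_cut)) if rs else 0, len(rs)),
        "prediction": (n_pos, len(calls)),
    }
    return PartialScores(
        ectopic=partial_ectopic(ec, cfg.fc_down),
        knockout=partial_knockout(ko, cfg.fc_up),
        correlation=partial_correlation(rs, cfg.r_cut),
        prediction=partial_prediction(calls.values()) if has_any else None,
        counts=counts,
    )
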