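"""Enrichment analyses: preranked GSEA and hypergeometric over-representation.

Three uses:

* benchmarking -- for every miRNA with enough experimentally validated
  targets, a preranked GSEA asks whether the validated set concentrates
  at the top of that miRNA's composite-score ranking;
* gene-set annotation of a miRNA's top-k target set against a GMT
  collection (one-sided hypergeometric ORA with BH correction);
* user gene lists -- ORA of a user-supplied list against every miRNA's
  top-k target set, ranking miRNAs by how strongly their predicted
  targets over-represent the list.

The GSEA enrichment statistic is the weighted Kolmogorov-Smirnov running
sum (weight exponent 1): walking down the ranking, hits advance the sum
proportionally to |score| and misses retreat it by 1/(N - K); the ES is
the maximum signed excursion.  P-values come from gene-label permutations
of set membership with +1 smoothing, so p >= 1/(n_perm + 1); NES divides
the ES by the mean |permuted ES| of matching sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bundle import ValidatedTargetCatalog, normalize_gene
from .scoring import ScoreTable
from .target_scores import extract_top_targets


@dataclass
class EnrichmentResult:
    """One gene set's enrichment against a ranking (GSEA) or a query list (ORA)."""

    set_name: str
    es: float | None = None
    nes: float | None = None
    p: float = 1.0
    fdr: float | None = None
    overlap_genes: list[str] = field(default_factory=list)
    k: int | None = None  # overlap size (ORA)
    n: int | None = None  # query size in universe (ORA)
    K: int | None = None  # set size in universe (ORA)
    N: int | None = None  # universe size (ORA)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    from gseapy.parser import read_gmt as _read_gmt

    raw = _read_gmt(str(path))
    return {name: {normalize_gene(g) for g in genes} for name, genes in raw.items()}


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# enrichment score


def enrichment_score(
    ranked_genes: list[str] | np.ndarray,
    ranked_scores: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> float:
    """Weighted KS running-sum enrichment score of a set in a ranking.

    ``ranked_genes``/``ranked_scores`` must be ordered best-first.  A set
    covering the whole ranking leaves no misses to normalise against; its
    ES is defined as 0 (with a warning).
    """
    genes = np.asarray(ranked_genes)
    scores = np.asarray(ranked_scores, dtype=float)
    n = genes.size
    hit = np.isin(genes, list(gene_set))
    n_hit = int(hit.sum())
    if n_hit == 0:
        return 0.0
    if n_hit == n:
        warnings.warn("gene set covers the entire ranking; ES defined as 0", stacklevel=2)
        return 0.0
    pos = np.flatnonzero(hit)
    w = np.abs(scores[pos]) ** weight
    total = w.sum()
    if total == 0:
        w = np.ones_like(w)  # all-zero scores degrade to unweighted KS
        total = w.sum()
    return _es_from_positions(pos, w, total, n)


def _es_from_positions(
    pos: np.ndarray, w: np.ndarray, total_w: float, n: int
) -> float:
    """Signed maximal excursion of the running sum, evaluated at hit positions.

    The running sum is piecewise monotone between hits, so its extrema
    occur immediately after a hit (candidate maxima) or immediately
    before one / at the end (candidate minima).
    """
    k = pos.size
    miss_step = 1.0 / (n - k)
    hit_cum = np.cumsum(w) / total_w
    miss_before = (pos - np.arange(k)) * miss_step       # misses seen before each hit
    after_hit = hit_cum - miss_before                    # value just after each hit
    before_hit = np.r_[0.0, hit_cum[:-1]] - miss_before  # value just before each hit
    es_max = float(after_hit.max())
    es_min = float(min(before_hit.min(), hit_cum[-1] - 1.0))
    # the larger excursion wins; exact ties (to within accumulation error)
    # resolve to the positive excursion so the sign is deterministic
    return es_max if es_max >= -es_min - 1e-12 else es_min


def preranked_gsea(
    ranked: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "",
    weight: float = 1.0,
) -> EnrichmentResult:
    """Preranked GSEA of one gene set against a descending ranking.

    ``ranked`` maps gene id -> score, ordered best-first (ties must
    already be broken deterministically, e.g. by gene id).  P-values are
    sign-matched permutation tails with +1 smoothing over gene-label
    permutations of set membership.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 (got {n_perm})")
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    n = genes.size
    overlap = sorted(set(genes) & gene_set)
    if not overlap:
        warnings.warn(f"gene set {set_name!r} has no overlap with the ranking", stacklevel=2)
        return EnrichmentResult(set_name=set_name, es=None, nes=None, p=1.0,
                                overlap_genes=[])
    es = enrichment_score(genes, scores, gene_set, weight)
    k = len(overlap)
    if k == n:
        return EnrichmentResult(set_name=set_name, es=0.0, nes=0.0, p=1.0,
                                overlap_genes=overlap)

    rng = np.random.default_rng(seed)
    abs_scores = np.abs(scores) ** weight
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        w = abs_scores[pos]
        total = w.sum()
        if total == 0:
            w = np.ones_like(w)
            total = float(k)
        perm_es[i] = _es_from_positions(pos, w, total, n)

    if es >= 0:
        same = perm_es[perm_es >= 0]
        n_extreme = int((same >= es).sum())
    else:
        same = perm_es[perm_es < 0]
        n_extreme = int((same <= es).sum())
    p = (1.0 + n_extreme) / (len(same) + 1.0)
    denom = float(np.mean(np.abs(same))) if len(same) else float(np.mean(np.abs(perm_es)))
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(set_name=set_name, es=es, nes=nes, p=p, overlap_genes=overlap)


# ---------------------------------------------------------------------------
# validated-target benchmark


def benchmark_validated(
    score_table: ScoreTable,
    catalog: ValidatedTargetCatalog,
    min_targets: int = 10,
    assay: str = "luciferase_reporter",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Preranked GSEA of validated targets in every qualifying miRNA's ranking.

    A miRNA qualifies when the catalog holds at least ``min_targets``
    targets validated by the given assay that are present in the miRNA's
    scored ranking.  Returns one row per qualifying miRNA with ES, NES,
    permutation p and BH FDR across miRNAs, plus a ``significant`` flag
    at ``alpha`` on the FDR.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    mirnas = [m for m in score_table.mirnas]
    child_seeds = ss.spawn(len(mirnas))
    for mirna, child in zip(mirnas, child_seeds):
        validated = catalog.targets_of(mirna, assay=assay)
        if len(validated) < min_targets:
            continue
        ranked = score_table.ranked_list(mirna)
        in_ranking = validated & set(ranked.index)
        if len(in_ranking) < min_targets:
            continue
        res = preranked_gsea(
            ranked, in_ranking, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)), set_name=mirna,
        )
        rows.append(
            {
                "mirna": mirna, "n_validated": len(in_ranking),
                "es": res.es, "nes": res.nes, "p": res.p,
            }
        )
    if not rows:
        warnings.warn(
            f"no miRNA has >= {min_targets} validated targets in the ranking",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["mirna", "n_validated", "es", "nes", "p", "fdr", "significant"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < alpha
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# over-representation analysis


def ora_enrich(
    query: list[str] | set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query list in gene sets.

    For each set the p-value is P[X >= k] with X ~ Hypergeometric(N, K, n)
    where N is the universe size, K the set size within the universe, n
    the query size within the universe and k their overlap.  BH FDR is
    computed across the sets.
    """
    query_set = {normalize_gene(g) for g in query}
    if not query_set:
        raise ValueError("query gene list is empty")
    universe = {normalize_gene(g) for g in universe}
    q = query_set & universe
    if not q:
        raise ValueError("query list has no overlap with the universe")
    n_u = len(universe)
    rows = []
    for name in sorted(sets):
        members = {normalize_gene(g) for g in sets[name]} & universe
        overlap = sorted(q & members)
        k, big_k, n = len(overlap), len(members), len(q)
        p = float(stats.hypergeom.sf(k - 1, n_u, big_k, n)) if big_k else 1.0
        rows.append(
            {
                "set_name": name, "k": k, "n": n, "K": big_k, "N": n_u,
                "p": min(p, 1.0), "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["fdr", "p", "set_name"], kind="mergesort").reset_index(drop=True)


def user_list_mirna_enrichment(
    user_genes: list[str],
    score_table: ScoreTable,
    k: int = 1000,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Which miRNAs' top-k predicted target sets over-represent a user gene list.

    The universe defaults to every gene present in the score table.
    Returns the ORA table (one row per miRNA, ranked by FDR).
    """
    if universe is None:
        universe = set(score_table.genes)
    sets = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mirna in score_table.mirnas:
            sets[mirna] = set(extract_top_targets(score_table, mirna, k))
    return ora_enrich(user_genes, sets, universe)
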