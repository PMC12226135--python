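"""Cancer-relevance annotation of genes and miRNAs.

Four annotations are computed per feature and cancer type:

* tumour-vs-normal differential expression with an empirical-Bayes
  moderated t-statistic (gene-wise variances are shrunk towards a pooled
  prior fitted by moment matching on log variances, which stabilises
  inference when per-group sample sizes are small);
* overall-survival association, dichotomising expression at the cutoff
  that maximises the standardised log-rank statistic over candidate
  splits between the 10th and 90th expression percentiles (the reported
  p-value is the naive log-rank p at the selected cutoff, which is
  anti-conservative under the null -- a documented property of
  optimal-cutoff survival screening, deliberately left uncorrected to
  match common practice);
* cell-line dependency: a gene is flagged dependent in a cancer type when
  at least 10 % of its cell lines show a gene-effect score strictly below
  -0.5 (effects below -1 additionally count towards an essentiality
  fraction);
* druggability: membership in a curated druggable-gene list.

The survival machinery (log-rank statistic over many cutoffs and a
one-parameter Cox fit for the hazard ratio of the binary high/low split)
is implemented directly on cumulative risk-set sums so that scanning
thousands of features stays fast; it is cross-checked against lifelines
in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .bundle import normalize_gene, write_tsv
from .config import ConfigurationError, RunConfig

UP = "up_in_tumor"
DOWN = "down_in_tumor"
POOR = "poor_with_high"
GOOD = "good_with_high"
NS = "ns"


@dataclass
class DEResult:
    entity: str
    feature: str
    log2_fold_change: float | None
    t: float | None
    p: float | None
    fdr: float | None
    direction: str  # UP / DOWN / NS
    undetermined: bool = False


@dataclass
class SurvivalAssoc:
    entity: str
    feature: str
    cutoff: float | None
    hazard_ratio: float | None
    logrank_p: float | None
    direction: str  # POOR / GOOD / NS
    undetermined: bool = False


@dataclass
class DependencyCall:
    entity: str
    gene: str
    screen: str  # "crispr" | "rnai"
    fraction_dependent: float
    dependent: bool
    essential_fraction: float
    n_lines: int = 0


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed variances.

    Returns (d0, s0_sq): the prior degrees of freedom and prior variance.
    With fewer than two usable variances no prior can be estimated and
    d0 = 0 (no shrinkage).
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        # variances less dispersed than a chi-square: infinitely strong prior,
        # whose scale is best estimated by the arithmetic mean of the variances
        return math.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_t_two_group(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated two-sample t-test per row of two feature x sample matrices.

    Returns (diff, t, p): mean difference (x - y), moderated t statistics
    and two-sided p-values.  Variances are pooled within rows and shrunk
    towards the moment-matched prior; the t reference has df + d0 degrees
    of freedom.  With a single row (no prior estimable) the statistic is
    the ordinary two-sample t.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs at least two samples")
    df = n1 + n2 - 2
    diff = x.mean(axis=1) - y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    d0, s0_sq = _fit_f_dist(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 > 0:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        s2_post = s2
    # total df capped at the pooled residual df across features, so the
    # reference stays a t-distribution even under an infinitely strong prior
    df_total = min(df + d0, x.shape[0] * df) if d0 > 0 else df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return diff, t, np.clip(p, np.nextafter(0, 1), 1.0)


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    entity: str = "",
    alpha: float = 0.05,
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """Tumour-vs-normal differential expression over a feature x sample matrix.

    ``expr`` is log2-scale expression (rows: genes or miRNAs, columns:
    samples); ``labels`` assigns each column to ``"tumor"`` or
    ``"normal"``.  Features whose expression is constant, or whose median
    is zero (the low-expression regime where the contrast cannot be
    evaluated), are marked ``undetermined`` and excluded from testing.

    Returns a DataFrame with columns entity, feature, log2_fold_change,
    t, p, fdr, direction, undetermined.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    groups = set(labels.unique())
    if not groups <= {"tumor", "normal"}:
        raise ConfigurationError(f"labels must be 'tumor'/'normal', got {sorted(groups)}")
    tumor = expr.loc[:, labels == "tumor"]
    normal = expr.loc[:, labels == "normal"]
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ConfigurationError(
            f"need >=2 samples per group (tumor={tumor.shape[1]}, normal={normal.shape[1]})"
        )

    values = expr.to_numpy(dtype=float)
    undetermined = (np.ptp(values, axis=1) == 0) | (np.median(values, axis=1) == 0)

    out = pd.DataFrame(
        {
            "entity": entity,
            "feature": expr.index.astype(str),
            "log2_fold_change": np.nan,
            "t": np.nan,
            "p": np.nan,
            "fdr": np.nan,
            "direction": NS,
            "undetermined": undetermined,
        }
    )
    tested = ~undetermined
    if tested.any():
        diff, t, p = moderated_t_two_group(
            tumor.to_numpy(dtype=float)[tested], normal.to_numpy(dtype=float)[tested]
        )
        fdr = multipletests(p, method="fdr_bh")[1]
        out.loc[tested, "log2_fold_change"] = diff
        out.loc[tested, "t"] = t
        out.loc[tested, "p"] = p
        out.loc[tested, "fdr"] = fdr
        crit = fdr if use_adjusted_p else p
        sig = crit < alpha
        direction = np.where(sig & (diff > 0), UP, np.where(sig & (diff < 0), DOWN, NS))
        out.loc[tested, "direction"] = direction
    return out


# ---------------------------------------------------------------------------
# survival: fast log-rank over cutoffs + binary Cox HR


def _risk_tables(time: np.ndarray, event: np.ndarray):
    """Aggregate to distinct times, sorted ascending.

    Returns (order, starts, d, n) where ``order`` sorts samples by time,
    ``starts`` are the segment starts of distinct times in that order,
    ``d`` the number of events and ``n`` the number at risk at each
    distinct time.
    """
    order = np.argsort(time, kind="mergesort")
    ts = time[order]
    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    d = np.add.reduceat(event[order].astype(float), starts)
    n_total = len(time)
    n = n_total - starts.astype(float)
    return order, starts, d, n


def _logrank_scan(
    expr: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cutoffs: np.ndarray,
) -> np.ndarray:
    """Standardised log-rank z statistic of (expr > cutoff) for each cutoff."""
    order, starts, d, n = _risk_tables(time, event)
    ev_sorted = event[order].astype(float)
    x_sorted = expr[order]
    g = (x_sorted[None, :] > cutoffs[:, None]).astype(float)  # C x samples
    suffix = np.cumsum(g[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]
    d1 = np.add.reduceat(g * ev_sorted[None, :], starts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n[None, :]
        e1 = d[None, :] * frac
        v = d[None, :] * frac * (1.0 - frac) * (n[None, :] - d[None, :]) / (n[None, :] - 1.0)
    v = np.where(n[None, :] > 1, v, 0.0)
    o_minus_e = (d1 - e1).sum(axis=1)
    var = v.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = o_minus_e / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def logrank_test_binary(
    high: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (z, p) with z > 0 for worse high group."""
    z = float(_logrank_scan(high.astype(float), time, event, np.asarray([0.5]))[0])
    p = float(stats.chi2.sf(z * z, 1)) if z != 0 else 1.0
    return z, max(p, np.nextafter(0, 1))


def cox_hr_binary(
    high: np.ndarray, time: np.ndarray, event: np.ndarray,
    max_iter: int = 40, tol: float = 1e-10,
) -> float:
    """Hazard ratio (high vs low) from a one-covariate Cox fit, Breslow ties.

    Newton iterations on the scalar log hazard ratio; beta is clipped to
    +/-10 (HR ~ 2.2e4) which covers complete separation.
    """
    order, starts, d, n = _risk_tables(time, event)
    g = high[order].astype(float)
    ev = event[order].astype(float)
    suffix = np.cumsum(g[::-1])[::-1]
    n1 = suffix[starts]          # group-1 at risk at each distinct time
    n0 = n - n1
    d1 = np.add.reduceat(g * ev, starts)
    o1 = float(d1.sum())

    beta = 0.0
    for _ in range(max_iter):
        eb = math.exp(beta)
        denom = n0 + eb * n1
        frac = np.where(denom > 0, eb * n1 / denom, 0.0)
        u = o1 - float((d * frac).sum())
        i_info = float((d * frac * (1.0 - frac)).sum())
        if i_info <= 1e-12:
            break
        step = u / i_info
        beta = float(np.clip(beta + step, -10.0, 10.0))
        if abs(step) < tol or abs(beta) >= 10.0:
            break
    return math.exp(beta)


def survival_association(
    expr: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    entity: str = "",
    feature: str = "",
    scan: tuple[float, float] = (0.10, 0.90),
    min_group_frac: float = 0.10,
    alpha: float = 0.05,
) -> SurvivalAssoc:
    """Optimal-cutoff overall-survival association for one feature.

    Candidate cutoffs are the unique expression values between the scan
    quantiles whose high/low split leaves each group at least
    ``min_group_frac`` of the cohort; the cutoff maximising |z| of the
    log-rank statistic is selected.  The returned p-value is the naive
    log-rank p at that cutoff (anti-conservative under the null; see
    module docstring).  Features with constant or zero-median expression,
    or cohorts without events, are returned ``undetermined``.
    """
    x = np.asarray(expr, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    und = SurvivalAssoc(entity, feature, None, None, None, NS, undetermined=True)
    if event.sum() < 1 or np.ptp(x) == 0 or np.median(x) == 0:
        return und
    cutoffs = _candidate_cutoffs(x, scan, min_group_frac)
    if cutoffs.size == 0:
        return und
    z = _logrank_scan(x, time, event, cutoffs)
    best = int(np.argmax(np.abs(z)))
    cutoff = float(cutoffs[best])
    high = x > cutoff
    z_best, p = logrank_test_binary(high, time, event)
    hr = cox_hr_binary(high, time, event)
    if p < alpha:
        direction = POOR if hr > 1 else GOOD
    else:
        direction = NS
    return SurvivalAssoc(entity, feature, cutoff, hr, p, direction, undetermined=False)


def _candidate_cutoffs(
    x: np.ndarray, scan: tuple[float, float], min_group_frac: float
) -> np.ndarray:
    lo, hi = np.quantile(x, scan[0]), np.quantile(x, scan[1])
    uniq = np.unique(x)
    cand = uniq[(uniq >= lo) & (uniq <= hi)]
    n = len(x)
    min_n = max(1, math.ceil(min_group_frac * n))
    keep = []
    for c in cand:
        n_high = int((x > c).sum())
        if min_n <= n_high <= n - min_n:
            keep.append(c)
    return np.asarray(keep, dtype=float)


def survival_screen(
    expr: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    entity: str = "",
    scan: tuple[float, float] = (0.10, 0.90),
    min_group_frac: float = 0.10,
    alpha: float = 0.05,
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """Optimal-cutoff survival association for every row of a feature matrix.

    Direction calls use BH-adjusted p-values across the screened features
    by default.  Returns one row per feature (entity, feature, cutoff,
    hazard_ratio, logrank_p, fdr, direction, undetermined).
    """
    rows = []
    for feat in expr.index:
        assoc = survival_association(
            expr.loc[feat].to_numpy(), time, event,
            entity=entity, feature=str(feat), scan=scan,
            min_group_frac=min_group_frac, alpha=alpha,
        )
        rows.append(assoc)
    df = pd.DataFrame(
        {
            "entity": entity,
            "feature": [a.feature for a in rows],
            "cutoff": [a.cutoff for a in rows],
            "hazard_ratio": [a.hazard_ratio for a in rows],
            "logrank_p": [a.logrank_p for a in rows],
            "fdr": np.nan,
            "direction": NS,
            "undetermined": [a.undetermined for a in rows],
        }
    )
    tested = ~df["undetermined"].to_numpy()
    if tested.any():
        p = df.loc[tested, "logrank_p"].to_numpy(dtype=float)
        fdr = multipletests(p, method="fdr_bh")[1]
        df.loc[tested, "fdr"] = fdr
        crit = fdr if use_adjusted_p else p
        hr = df.loc[tested, "hazard_ratio"].to_numpy(dtype=float)
        sig = crit < alpha
        df.loc[tested, "direction"] = np.where(
            sig & (hr > 1), POOR, np.where(sig & (hr < 1), GOOD, NS)
        )
    return df


# ---------------------------------------------------------------------------
# dependency & druggability


def dependency_call(
    effects: np.ndarray | list[float],
    entity: str,
    gene: str = "",
    screen: str = "crispr",
    effect_cut: float = -0.5,
    frac_cut: float = 0.10,
    essential_cut: float = -1.0,
) -> DependencyCall:
    """Dependency flag for one gene in one cancer type.

    A line counts as dependent when its gene-effect score is strictly
    below ``effect_cut``; the gene is flagged when the dependent fraction
    reaches ``frac_cut`` (inclusive).
    """
    eff = np.asarray(list(effects), dtype=float)
    if eff.size == 0:
        raise ConfigurationError(f"no cell lines for gene {gene!r} in {entity!r}")
    k = int((eff < effect_cut).sum())
    n = eff.size
    frac = k / n
    ess = float((eff < essential_cut).sum()) / n
    return DependencyCall(
        entity=entity, gene=gene, screen=screen,
        fraction_dependent=frac, dependent=frac >= frac_cut,
        essential_fraction=ess, n_lines=n,
    )


def dependency_screen(
    depmap: pd.DataFrame,
    effect_cut: float = -0.5,
    frac_cut: float = 0.10,
) -> pd.DataFrame:
    """Dependency calls for every (entity, gene, screen) group of a long table.

    ``depmap`` columns: entity, cell_line, gene, effect, screen.
    """
    for col in ("entity", "cell_line", "gene", "effect", "screen"):
        if col not in depmap.columns:
            raise ConfigurationError(f"dependency table lacks column {col!r}")
    g = depmap.groupby(["entity", "gene", "screen"], sort=True)["effect"]
    out = g.agg(
        n_lines="count",
        fraction_dependent=lambda e: float((e < effect_cut).sum()) / len(e),
        essential_fraction=lambda e: float((e < -1.0).sum()) / len(e),
    ).reset_index()
    out["dependent"] = out["fraction_dependent"] >= frac_cut
    return out


def druggability_flag(gene: str, druggable: set[str]) -> bool:
    """Membership of a gene in the druggable-gene list."""
    if not druggable:
        warnings.warn("druggable gene list is empty; every gene flags False", stacklevel=2)
        return False
    return normalize_gene(gene) in druggable


# ---------------------------------------------------------------------------
# annotation container & IO


@dataclass
class Annotations:
    """Per-entity clinical annotations for genes and miRNAs.

    ``de`` and ``survival`` are long DataFrames (one row per entity x
    feature); ``dependency`` one row per entity x gene x screen;
    ``druggable`` a set of gene symbols.
    """

    de: pd.DataFrame
    survival: pd.DataFrame
    dependency: pd.DataFrame
    druggable: set[str] = field(default_factory=set)

    def de_for(self, entity: str) -> pd.DataFrame:
        sub = self.de[self.de["entity"] == entity]
        if sub.empty:
            raise LookupError(f"no differential-expression results for entity {entity!r}")
        return sub

    def survival_for(self, entity: str) -> pd.DataFrame:
        sub = self.survival[self.survival["entity"] == entity]
        if sub.empty:
            raise LookupError(f"no survival results for entity {entity!r}")
        return sub

    @property
    def de_entities(self) -> list[str]:
        return sorted(self.de["entity"].unique())

    @property
    def survival_entities(self) -> list[str]:
        return sorted(self.survival["entity"].unique())

    def write(self, out_dir: str | Path, config: RunConfig | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = [f"config: {config.to_json()}"] if config else []
        write_tsv(self.de, out / "de.tsv", header)
        write_tsv(self.survival, out / "survival.tsv", header)
        write_tsv(self.dependency, out / "dependency.tsv", header)
        with open(out / "druggable.txt", "w") as fh:
            for gene in sorted(self.druggable):
                fh.write(gene + "\n")

    @classmethod
    def read(cls, annot_dir: str | Path) -> "Annotations":
        d = Path(annot_dir)
        de = pd.read_csv(d / "de.tsv", sep="\t", comment="#")
        surv = pd.read_csv(d / "survival.tsv", sep="\t", comment="#")
        dep = pd.read_csv(d / "dependency.tsv", sep="\t", comment="#")
        for df in (de, surv):
            df["feature"] = df["feature"].astype(str)
            df["entity"] = df["entity"].astype(str)
        dep["gene"] = dep["gene"].astype(str)
        druggable: set[str] = set()
        drug_path = d / "druggable.txt"
        if drug_path.exists():
            with open(drug_path) as fh:
                druggable = {normalize_gene(s) for s in fh.read().split() if s.strip()}
        return cls(de=de, survival=surv, dependency=dep, druggable=druggable)


def annotate_clinical(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    depmap: pd.DataFrame | None = None,
    druggable: set[str] | None = None,
    config: RunConfig | None = None,
) -> Annotations:
    """Full clinical annotation from an expression matrix and its sample sidecar.

    ``samples`` columns: sample, entity, cohort ("tumor_normal" or
    "survival"), group ("tumor"/"normal" within tumor_normal), time,
    event (within survival).  Differential expression and survival are
    computed per entity across every feature row of ``expr``.
    """
    cfg = config or RunConfig()
    samples = samples.set_index("sample") if "sample" in samples.columns else samples
    de_frames, surv_frames = [], []
    for entity in sorted(samples["entity"].unique()):
        ent = samples[samples["entity"] == entity]
        tn = ent[ent["cohort"] == "tumor_normal"]
        if len(tn) >= 4 and {"tumor", "normal"} <= set(tn["group"]):
            de_frames.append(
                differential_expression(
                    expr[tn.index], tn["group"], entity=entity,
                    alpha=cfg.alpha, use_adjusted_p=cfg.use_adjusted_p,
                )
            )
        sv = ent[ent["cohort"] == "survival"]
        if len(sv) >= 10 and sv["event"].sum() >= 1:
            surv_frames.append(
                survival_screen(
                    expr[sv.index],
                    sv["time"].to_numpy(dtype=float),
                    sv["event"].to_numpy(dtype=int),
                    entity=entity, alpha=cfg.alpha,
                    use_adjusted_p=cfg.use_adjusted_p,
                )
            )
    de = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame(
        columns=["entity", "feature", "log2_fold_change", "t", "p", "fdr",
                 "direction", "undetermined"]
    )
    surv = pd.concat(surv_frames, ignore_index=True) if surv_frames else pd.DataFrame(
        columns=["entity", "feature", "cutoff", "hazard_ratio", "logrank_p",
                 "fdr", "direction", "undetermined"]
    )
    dep = (
        dependency_screen(depmap, cfg.dep_effect, cfg.dep_frac)
        if depmap is not None and len(depmap)
        else pd.DataFrame(
            columns=["entity", "gene", "screen", "n_lines",
                     "fraction_dependent", "essential_fraction", "dependent"]
        )
    )
    return Annotations(de=de, survival=surv, dependency=dep, druggable=druggable or set())
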