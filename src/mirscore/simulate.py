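"""Seeded generator of complete synthetic inputs with planted ground truth.

The generator emulates the structure of the real evidence corpus at desk
scale: every miRNA receives a handful of ectopic-expression datasets
(default 4 per miRNA, mirroring the ~4 studies per miRNA of the real
compilation) and knockout/knockdown datasets (default 3), dense per-entity
miRNA x mRNA correlation panels, and binary calls from a 10-algorithm
prediction complement.  A planted fraction of miRNA-gene pairs are true
targets: their ectopic fold changes are log-normal around a genuine
repression (default 0.5), knockout fold changes around a genuine induction
(default 2.0), correlations Fisher-z-jittered around a genuine negative r
(default -0.4) and prediction support binomial with high success
probability; decoys draw the same noise centred on no effect.

Each miRNA is also assigned a clinical class -- tumour-suppressive,
oncogenic or neutral.  The clinical generator links the class to the data:
targets of a tumour-suppressive miRNA are planted up-in-tumour /
poor-survival / frequently dependent (the constellation expected of
oncogenes), and vice versa.  Survival uses a latent patient risk score
with exponential event times and uniform censoring, so that every planted
feature's expression can load on the same cohort's risk jointly.

Everything is reproducible from the seed; the ground-truth ledger records
every planted effect so tests can recompute expected summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import (
    ECTOPIC,
    KNOCKOUT,
    CorrelationPanel,
    EvidenceBundle,
    FoldChangeDataset,
    PredictionCalls,
    ValidatedTargetCatalog,
    write_tsv,
)
from .config import ConfigurationError

SUPPRESSIVE = "suppressive"
ONCOGENIC = "oncogenic"
NEUTRAL = "neutral"

DEFAULT_ALGORITHMS = [f"algo{i:02d}" for i in range(1, 11)]


@dataclass
class EffectParams:
    """Planted effect sizes and noise levels of the generator.

    Fold-change noise is log-normal (sigma on the natural-log scale);
    correlation noise is additive on the Fisher-z scale.
    """

    repression_fold: float = 0.5    # planted ectopic fold change of true targets
    induction_fold: float = 2.0     # planted knockout fold change of true targets
    target_r: float = -0.4          # planted miRNA/target correlation
    fc_sigma: float = 0.2           # log-scale fold-change noise
    r_sigma: float = 0.15           # Fisher-z correlation noise
    pred_support_p: float = 0.8     # per-algorithm call probability, true targets
    decoy_pred_p: float = 0.05      # per-algorithm call probability, decoys
    de_log2fc: float = 1.5          # planted tumour/normal shift of clinical genes
    survival_loading: float = 1.0   # expression loading on the latent risk score
    dependency_fraction: float = 0.2  # planted dependent-line fraction
    druggable_p: float = 0.3        # probability a planted clinical gene is druggable


@dataclass
class GroundTruthLedger:
    """Everything the generator planted, sufficient to recompute expectations."""

    seed: int
    mirnas: list[str]
    genes: list[str]
    entities: list[str]
    planted_targets: dict[str, list[str]]          # mirna -> planted target genes
    mirna_class: dict[str, str]                    # mirna -> SUPPRESSIVE/ONCOGENIC/NEUTRAL
    gene_profile: dict[str, str]                   # gene -> "oncogene"/"suppressor"/"null"
    druggable: list[str]
    effects: EffectParams = field(default_factory=EffectParams)

    def is_planted(self, mirna: str, gene: str) -> bool:
        return gene in set(self.planted_targets.get(mirna, ()))

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthLedger":
        with open(path) as fh:
            d = json.load(fh)
        d["effects"] = EffectParams(**d["effects"])
        return cls(**d)


def _check_positive(**kwargs: int) -> None:
    for name, val in kwargs.items():
        if val < 1:
            raise ConfigurationError(f"{name} must be >= 1 (got {val})")


def generate_evidence(
    n_mirnas: int = 20,
    n_genes: int = 2000,
    n_ectopic_per_mirna: int = 4,
    n_ko_per_mirna: int = 3,
    n_entities: int = 10,
    planted_fraction: float = 0.05,
    effects: EffectParams | None = None,
    seed: int = 0,
) -> tuple[EvidenceBundle, GroundTruthLedger]:
    """Generate a full evidence bundle with planted true targets.

    Default sizes (20 miRNAs x 2000 genes x 10 entities, ~4 ectopic and
    3 knockout studies per miRNA) scale the real corpus down while
    keeping its per-miRNA study counts.
    """
    _check_positive(
        n_mirnas=n_mirnas, n_genes=n_genes,
        n_ectopic_per_mirna=n_ectopic_per_mirna,
        n_ko_per_mirna=n_ko_per_mirna, n_entities=n_entities,
    )
    if not (0.0 < planted_fraction < 1.0):
        raise ConfigurationError(
            f"planted_fraction must lie in (0, 1) (got {planted_fraction})"
        )
    eff = effects or EffectParams()
    rng = np.random.default_rng(seed)

    mirnas = [f"mir-s{i + 1:03d}" for i in range(n_mirnas)]
    genes = [f"SYN{i + 1:05d}" for i in range(n_genes)]
    entities = [f"CT{i + 1:02d}" for i in range(n_entities)]
    gene_arr = np.asarray(genes)

    n_planted = max(1, round(planted_fraction * n_genes))
    planted: dict[str, list[str]] = {}
    for m in mirnas:
        planted[m] = sorted(rng.choice(gene_arr, size=n_planted, replace=False))

    # clinical classes: a quarter suppressive, a quarter oncogenic, rest neutral
    classes = np.array([NEUTRAL] * n_mirnas, dtype=object)
    n_quarter = max(1, n_mirnas // 4)
    classes[:n_quarter] = SUPPRESSIVE
    classes[n_quarter:2 * n_quarter] = ONCOGENIC
    rng.shuffle(classes)
    mirna_class = dict(zip(mirnas, classes))

    # planted targets inherit the opposite profile of their miRNA's class;
    # the first claiming miRNA wins on conflicts
    gene_profile: dict[str, str] = {}
    for m in mirnas:
        profile = {SUPPRESSIVE: "oncogene", ONCOGENIC: "suppressor", NEUTRAL: "null"}[
            mirna_class[m]
        ]
        for g in planted[m]:
            gene_profile.setdefault(g, profile)
    for g in genes:
        gene_profile.setdefault(g, "null")

    druggable = sorted(
        g for g in genes
        if gene_profile[g] != "null" and rng.random() < eff.druggable_p
    )

    planted_mask = {
        m: np.isin(gene_arr, planted[m]) for m in mirnas
    }

    ectopic: list[FoldChangeDataset] = []
    knockout: list[FoldChangeDataset] = []
    ds_counter = 0
    for m in mirnas:
        mask = planted_mask[m]
        for _ in range(n_ectopic_per_mirna):
            ds_counter += 1
            noise = rng.normal(0.0, eff.fc_sigma, n_genes)
            fc = np.exp(noise)
            fc[mask] *= eff.repression_fold
            ectopic.append(
                FoldChangeDataset(
                    dataset_id=f"EC{ds_counter:05d}", mirna=m, intervention=ECTOPIC,
                    fold_change=dict(zip(genes, fc)),
                    provenance=f"synthetic ectopic study for {m}",
                )
            )
        for _ in range(n_ko_per_mirna):
            ds_counter += 1
            noise = rng.normal(0.0, eff.fc_sigma, n_genes)
            fc = np.exp(noise)
            fc[mask] *= eff.induction_fold
            knockout.append(
                FoldChangeDataset(
                    dataset_id=f"KO{ds_counter:05d}", mirna=m, intervention=KNOCKOUT,
                    fold_change=dict(zip(genes, fc)),
                    provenance=f"synthetic knockout study for {m}",
                )
            )

    z_target = np.arctanh(eff.target_r)
    correlations: list[CorrelationPanel] = []
    for entity in entities:
        r_map: dict[tuple[str, str], float] = {}
        for m in mirnas:
            z = rng.normal(0.0, eff.r_sigma, n_genes)
            z[planted_mask[m]] += z_target
            r = np.tanh(z)
            r_map.update(zip(zip([m] * n_genes, genes), r))
        correlations.append(CorrelationPanel(cancer_type=entity, r=r_map))

    algorithms = list(DEFAULT_ALGORITHMS)
    calls: set[tuple[str, str, str]] = set()
    alg_arr = np.asarray(algorithms)
    for m in mirnas:
        mask = planted_mask[m]
        p_call = np.where(mask, eff.pred_support_p, eff.decoy_pred_p)
        hits = rng.random((len(algorithms), n_genes)) < p_call[None, :]
        for ai, alg in enumerate(alg_arr):
            for g in gene_arr[hits[ai]]:
                calls.add((str(alg), m, str(g)))

    bundle = EvidenceBundle(
        ectopic=ectopic,
        knockout=knockout,
        correlations=correlations,
        predictions=PredictionCalls(algorithms=algorithms, calls=calls),
        gene_universe=set(genes),
        mirna_universe=set(mirnas),
    )
    ledger = GroundTruthLedger(
        seed=seed, mirnas=mirnas, genes=genes, entities=entities,
        planted_targets=planted, mirna_class=mirna_class,
        gene_profile=gene_profile, druggable=druggable, effects=eff,
    )
    return bundle, ledger


def generate_clinical(
    ledger: GroundTruthLedger,
    n_tumor: int = 25,
    n_normal: int = 25,
    n_survival: int = 150,
    n_cell_lines: int = 40,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Clinical tables linked to the ledger's planted classes.

    Returns ``(expression, samples, depmap)``:

    * ``expression`` -- log2-scale feature x sample matrix over all genes
      and miRNAs and all entities' cohorts;
    * ``samples`` -- sidecar with sample, entity, cohort, group, time,
      event;
    * ``depmap`` -- long gene-effect table (entity, cell_line, gene,
      effect, screen) for CRISPR and RNAi screens.

    Oncogene-profile genes (and, via class symmetry, the miRNAs
    themselves) are planted up-in-tumour and poor-survival; suppressor
    profiles mirror them.  Survival times are exponential in a latent
    patient risk score on which planted features' expression loads.
    """
    _check_positive(
        n_tumor=n_tumor, n_normal=n_normal,
        n_survival=n_survival, n_cell_lines=n_cell_lines,
    )
    eff = ledger.effects
    rng = np.random.default_rng(ledger.seed + 1 if seed is None else seed)
    features = list(ledger.genes) + list(ledger.mirnas)

    # per-feature planted directions (+1 up-in-tumour/poor-survival, -1 mirror, 0 null)
    sign = np.zeros(len(features))
    for i, f in enumerate(features):
        if f in ledger.gene_profile:
            prof = ledger.gene_profile[f]
            sign[i] = {"oncogene": 1.0, "suppressor": -1.0, "null": 0.0}[prof]
    for i, m in enumerate(ledger.mirnas):
        cls = ledger.mirna_class[m]
        sign[len(ledger.genes) + i] = {
            SUPPRESSIVE: -1.0, ONCOGENIC: 1.0, NEUTRAL: 0.0
        }[cls]

    baseline = 6.0 + rng.normal(0.0, 1.0, len(features))

    expr_cols: dict[str, np.ndarray] = {}
    sample_rows = []
    for entity in ledger.entities:
        # tumour/normal cohort
        for grp, n_grp in (("tumor", n_tumor), ("normal", n_normal)):
            shift = sign * eff.de_log2fc if grp == "tumor" else np.zeros_like(sign)
            block = (
                baseline[:, None] + shift[:, None]
                + rng.normal(0.0, 1.0, (len(features), n_grp))
            )
            for j in range(n_grp):
                name = f"{entity}_{grp[0].upper()}{j + 1:03d}"
                expr_cols[name] = block[:, j]
                sample_rows.append((name, entity, "tumor_normal", grp, np.nan, np.nan))
        # survival cohort: latent risk -> exponential times, uniform censoring
        risk = rng.normal(0.0, 1.0, n_survival)
        rate = 0.1 * np.exp(risk)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, 30.0, n_survival)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        block = (
            baseline[:, None]
            + eff.survival_loading * np.outer(sign, risk)
            + rng.normal(0.0, 1.0, (len(features), n_survival))
        )
        for j in range(n_survival):
            name = f"{entity}_S{j + 1:03d}"
            expr_cols[name] = block[:, j]
            sample_rows.append((name, entity, "survival", "tumor", time[j], event[j]))

    expression = pd.DataFrame(expr_cols, index=features)
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "entity", "cohort", "group", "time", "event"]
    )

    # dependency: planted oncogene-profile genes are dependent in a fraction of lines
    dep_rows = []
    planted_dep = [g for g in ledger.genes if ledger.gene_profile[g] == "oncogene"]
    dep_genes = planted_dep + [
        g for g in ledger.genes if ledger.gene_profile[g] != "oncogene"
    ][: len(planted_dep)]  # equally many null genes as contrast
    for entity in ledger.entities:
        for screen in ("crispr", "rnai"):
            for g in dep_genes:
                f_dep = eff.dependency_fraction if ledger.gene_profile[g] == "oncogene" else 0.0
                dep_mask = rng.random(n_cell_lines) < f_dep
                effect = np.where(
                    dep_mask,
                    rng.normal(-0.9, 0.2, n_cell_lines),
                    rng.normal(0.0, 0.2, n_cell_lines),
                )
                for li in range(n_cell_lines):
                    dep_rows.append(
                        (entity, f"{entity}_{screen}_L{li + 1:03d}", g,
                         effect[li], screen)
                    )
    depmap = pd.DataFrame(
        dep_rows, columns=["entity", "cell_line", "gene", "effect", "screen"]
    )
    return expression, samples, depmap


def synthetic_validated_catalog(
    ledger: GroundTruthLedger,
    n_per_mirna: int = 15,
    seed: int | None = None,
) -> ValidatedTargetCatalog:
    """A synthetic stand-in for a validated-target catalog.

    Draws ``n_per_mirna`` of each miRNA's planted targets (all available
    when fewer) and labels them luciferase-validated with synthetic PMIDs.
    """
    rng = np.random.default_rng(ledger.seed + 2 if seed is None else seed)
    rows = []
    for m in ledger.mirnas:
        targets = list(ledger.planted_targets[m])
        take = min(n_per_mirna, len(targets))
        chosen = rng.choice(targets, size=take, replace=False)
        for i, g in enumerate(sorted(chosen)):
            rows.append((m, g, f"9{ledger.seed % 1000:03d}{i:04d}", "luciferase_reporter"))
    return ValidatedTargetCatalog(
        records=pd.DataFrame(rows, columns=["mirna", "gene", "pmid", "assay"])
    )


# ---------------------------------------------------------------------------
# fixture directory writer (the exact dialects the loaders read)


def write_fixture_dir(
    out_dir: str | Path,
    bundle: EvidenceBundle,
    ledger: GroundTruthLedger,
    expression: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    depmap: pd.DataFrame | None = None,
    catalog: ValidatedTargetCatalog | None = None,
) -> None:
    """Write a complete fixture directory consumable by every loader."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name, intervention in (("ectopic.tsv", ECTOPIC), ("knockout.tsv", KNOCKOUT)):
        frame = bundle.fold_change_frame(intervention)
        write_tsv(frame, out / name)
    write_tsv(bundle.correlation_frame(), out / "correlations.tsv")
    pred = bundle.prediction_frame().sort_values(
        ["algorithm", "mirna", "gene"], kind="mergesort"
    )
    write_tsv(pred, out / "predictions.tsv")
    (out / "algorithms.txt").write_text(
        "\n".join(bundle.predictions.algorithms) + "\n"
    )
    (out / "mirnas.txt").write_text("\n".join(sorted(bundle.mirna_universe)) + "\n")
    (out / "genes.txt").write_text("\n".join(sorted(bundle.gene_universe)) + "\n")
    meta = pd.DataFrame(
        [(ds.dataset_id, ds.provenance) for ds in bundle.ectopic + bundle.knockout],
        columns=["dataset_id", "provenance"],
    )
    write_tsv(meta, out / "datasets.tsv")
    ledger.to_json(out / "ledger.json")

    if expression is not None:
        write_tsv(expression.reset_index(names="feature"), out / "expression.tsv")
    if samples is not None:
        write_tsv(samples, out / "samples.tsv")
    if depmap is not None:
        write_tsv(depmap, out / "depmap.tsv")
    if catalog is not None:
        write_tsv(catalog.records, out / "validated.tsv")
    (out / "druggable.txt").write_text("\n".join(ledger.druggable) + "\n")
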