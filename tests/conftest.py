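"""Shared fixtures: small seeded synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirscore import (
    Annotations,
    compute_scores,
    generate_clinical,
    generate_evidence,
)
from mirscore.clinical import annotate_clinical
from mirscore.simulate import synthetic_validated_catalog


@pytest.fixture(scope="session")
def small_system():
    """A small planted evidence bundle with matching clinical data.

    6 miRNAs x 300 genes x 4 entities, default effect sizes, seed 2.
    Returns a dict with bundle, ledger, score table, clinical tables,
    annotations and a synthetic validated-target catalog.
    """
    bundle, ledger = generate_evidence(
        n_mirnas=6, n_genes=300, n_entities=4, seed=2
    )
    expression, samples, depmap = generate_clinical(
        ledger, n_tumor=15, n_normal=15, n_survival=80, n_cell_lines=20
    )
    table = compute_scores(bundle)
    annotations = annotate_clinical(
        expression, samples, depmap, set(ledger.druggable)
    )
    catalog = synthetic_validated_catalog(ledger)
    return {
        "bundle": bundle,
        "ledger": ledger,
        "table": table,
        "expression": expression,
        "samples": samples,
        "depmap": depmap,
        "annotations": annotations,
        "catalog": catalog,
    }


@pytest.fixture(scope="session")
def tiny_bundle_dir(tmp_path_factory):
    """A written-out tiny fixture directory for loader tests."""
    from mirscore.simulate import write_fixture_dir

    bundle, ledger = generate_evidence(
        n_mirnas=3, n_genes=40, n_ectopic_per_mirna=2, n_ko_per_mirna=1,
        n_entities=3, planted_fraction=0.1, seed=11,
    )
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_dir(out, bundle, ledger)
    return out, bundle, ledger
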