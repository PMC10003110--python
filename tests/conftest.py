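"""Shared fixtures: synthetic cohorts run once through the pipeline stages.

The planted and null cohorts are expensive enough (classifier evaluation,
pair screening) that they are computed once per session and shared between
module tests and the end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from deltapcc import diffcorr, ingest, metastasis, normalization, survival, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

PLANTED_SEED = 1
NULL_SEED = 0


def run_pair_stages(cohort, task="LNM", use_class_filter=True):
    """ingest -> normalize -> pair filtering -> ΔPCC table -> Wilcoxon screen."""
    classes = ingest.classify_cohort(cohort.clinical)
    labels = ingest.assign_labels(classes, task)
    normals = classes.index[classes == ingest.SampleClass.normal]
    counts = normalization.filter_low_expression(cohort.counts)
    cpm = normalization.cpm(counts)
    universe = diffcorr.build_pair_universe(cohort.annotation, cpm.values.index)
    if use_class_filter:
        pairs = diffcorr.class_correlation_filter(cpm.values, labels, universe)
    else:
        pairs = universe
    table = diffcorr.build_delta_table(cpm.values, labels, pairs, normals, task=task)
    screen = diffcorr.wilcoxon_screen(table, labels)
    return {
        "cohort": cohort,
        "classes": classes,
        "labels": labels,
        "normals": normals,
        "cpm": cpm,
        "universe": universe,
        "pairs": pairs,
        "table": table,
        "screen": screen,
    }


def run_survival_stages(run, alpha_adj=0.01):
    """Wilcoxon-kept pairs -> pair survival screen -> star networks."""
    from deltapcc import netbio

    kept = run["screen"].index[run["screen"]["kept"]]
    clinical = run["cohort"].clinical
    results = survival.screen_pairs(run["table"].loc[kept], clinical,
                                    alpha_adj=alpha_adj)
    significant = [r for r in results if r.kept]
    networks = netbio.build_networks(significant)
    networks = [
        n
        for n in (
            netbio.evaluate_network(n, run["table"], clinical) for n in networks
        )
        if n is not None
    ]
    selected = netbio.select_biomarkers(networks, alpha_adj=alpha_adj)
    return {"pair_results": results, "networks": networks, "selected": selected}


@pytest.fixture(scope="session")
def planted_run():
    cohort = synthetic.generate_cohort(synthetic.default_config(PLANTED_SEED))
    return run_pair_stages(cohort)


@pytest.fixture(scope="session")
def planted_survival(planted_run):
    return run_survival_stages(planted_run)


@pytest.fixture(scope="session")
def null_run():
    """No-signal cohort; the class correlation filter would usually keep
    nothing here, so the full pair universe feeds the downstream stages."""
    cohort = synthetic.generate_cohort(synthetic.null_config(NULL_SEED))
    return run_pair_stages(cohort, use_class_filter=False)


@pytest.fixture(scope="session")
def planted_evaluation(planted_run):
    """10-repeat stratified 70/30 evaluation on the planted cohort."""
    table, labels = planted_run["table"], planted_run["labels"]
    return metastasis.evaluate(
        table.T, labels.loc[table.columns], seed=PLANTED_SEED, screen_alpha=0.01
    )


@pytest.fixture(scope="session")
def null_evaluation(null_run):
    table, labels = null_run["table"], null_run["labels"]
    return metastasis.evaluate(
        table.T, labels.loc[table.columns], seed=NULL_SEED, screen_alpha=0.01
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def six_pair_fixture():
    """Constructed CPM data with six miRNA-RNA pairs of known filter fate.

    Pair layout (|PCC| in positive / negative tumor samples):
      p1 strong/weak -> kept, p2 weak/strong -> kept, p3 strong/strong with
      opposite signs -> removed, p4 weak/weak -> removed, p5 strong/strong
      same sign -> removed, p6 weak/weak -> removed. The expected filter
      output is exactly the symmetric difference {p1, p2}.
    """
    base = np.arange(1.0, 11.0)
    weak_a = np.array([6, 7, 1, 8, 4, 3, 5, 10, 2, 9.0])  # r(base, .) = 0.16
    weak_b = np.array([1, 10, 9, 5, 8, 3, 4, 6, 7, 2.0])  # r(base, .) = -0.21
    anti = 22.0 - 2.0 * base  # r(base, .) = -1, values stay positive

    layout = {
        ("m1", "r1"): (base, weak_a),
        ("m2", "r2"): (weak_b, base),
        ("m3", "r3"): (2.0 * base, anti),
        ("m4", "r4"): (weak_a, weak_b),
        ("m5", "r5"): (base, 3.0 * base),
        ("m6", "r6"): (weak_b, weak_a),
    }
    rows, genes = [], []
    for (mirna, rna), (y_pos, y_neg) in layout.items():
        genes += [mirna, rna]
        rows.append(np.concatenate([base, base]))  # miRNA: base in both classes
        rows.append(np.concatenate([y_pos, y_neg]))
    samples = [f"p{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
    cpm = pd.DataFrame(rows, index=genes, columns=samples)
    labels = pd.Series(["positive"] * 10 + ["negative"] * 10, index=samples)
    universe = pd.MultiIndex.from_tuples(list(layout), names=["mirna", "rna"])
    expected = {("m1", "r1"), ("m2", "r2")}
    return cpm, labels, universe, expected


def two_pass_pearson(x, y):
    """Independent straight-line Pearson oracle (explicit two-pass sums)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy) ** 0.5
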