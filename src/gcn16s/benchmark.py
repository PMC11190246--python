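"""Cross-validated comparison of copy-number estimators on one dataset.

Runs the stacked ensemble, the five phylogenetic hidden-state predictors and
the taxonomy aggregation baseline over shared stratified folds and reports
per-fold and mean RMSE for each — the desk-scale analogue of a full
cross-validated method comparison.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .phylo_estimator import predict as phylo_predict
from .stacked_model import SEMConfig, evaluate_rmse, sem_predict, sem_train
from .synthetic_data import Benchmark
from .taxonomy_estimator import build_taxonomy_tree, query_lineage

PHYLO_METHODS = ("ep", "sa", "pic", "mpr", "wscp")


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Label-quantile-stratified fold assignment (seeded)."""
    n = len(labels)
    rng = np.random.Generator(np.random.PCG64(seed))
    order = np.argsort(labels, kind="stable")
    assign = np.empty(n, dtype=int)
    for start in range(0, n, folds):
        block = order[start : start + folds]
        assign[block] = rng.permutation(folds)[: len(block)]
    return assign


def compare_methods(
    bench: Benchmark,
    folds: int = 5,
    sem_config: Optional[SEMConfig] = None,
    seed: int = 0,
    methods: tuple[str, ...] = ("sem", *PHYLO_METHODS, "taxonomy"),
) -> pd.DataFrame:
    """Mean cross-validated RMSE of each estimator on a simulated study.

    Every estimator sees the same folds: training tips provide labels (and
    lineages), test tips are queried. The phylogenetic methods receive the
    true tree with test tips unlabeled; the taxonomy baseline receives the
    training lineages; the stacked ensemble sees only the sequences.
    """
    tips = [r.id for r in bench.sequences.records]
    records = {r.id: r for r in bench.sequences.records}
    y = np.array([bench.traits[t] for t in tips])
    assign = stratified_folds(y, folds, seed)

    rows = []
    for f in range(folds):
        test_tips = [t for t, a in zip(tips, assign) if a == f]
        train_tips = [t for t, a in zip(tips, assign) if a != f]
        y_test = np.array([bench.traits[t] for t in test_tips])
        known = {t: bench.traits[t] for t in train_tips}

        if "sem" in methods:
            model = sem_train([records[t] for t in train_tips],
                              [bench.traits[t] for t in train_tips],
                              sem_config or SEMConfig.desk(seed=seed))
            pred = sem_predict(model, [records[t] for t in test_tips])
            rows.append({"method": "sem", "fold": f,
                         "rmse": evaluate_rmse(pred, y_test)})

        for m in PHYLO_METHODS:
            if m not in methods:
                continue
            preds = phylo_predict(m, bench.tree, known, test_tips)
            rows.append({"method": m, "fold": f,
                         "rmse": evaluate_rmse([preds[t] for t in test_tips], y_test)})

        if "taxonomy" in methods:
            root = build_taxonomy_tree([bench.lineages[t] for t in train_tips],
                                       [bench.traits[t] for t in train_tips])
            preds = [query_lineage(root, bench.lineages[t]) for t in test_tips]
            rows.append({"method": "taxonomy", "fold": f,
                         "rmse": evaluate_rmse(preds, y_test)})
    df = pd.DataFrame(rows)
    return (df.groupby("method")["rmse"].agg(mean_rmse="mean", sd_rmse="std")
            .reset_index())
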