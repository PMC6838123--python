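"""Canned study-scale experiments used by the acceptance checks.

These run the library end to end at the standard desk-scale study
conditions (400×400-bin planted fixture, expected depth 2×10⁶ read
pairs, 10% coverage) and return plain dictionaries/frames of the
quantities they measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import annotate as ann
from . import hic_matrix as hm
from . import synthetic as syn
from .autoencoder import TrainingConfig
from .conservation import enumerate_states
from .evaluation import accuracy, coverage_sweep

SWEEP_RATES = (0.4, 0.2, 0.1, 0.05, 0.02)


def conservation_enumeration(n_cell_types: int = 9) -> dict[str, int]:
    """Discrete entropy classes of cross-cell-type annotation vectors."""
    table = enumerate_states(n_cell_types)
    return {
        "distinct_entropy_values": len(table.entropies),
        "non_majority_classes": table.n_nc_classes,
        "total_states": table.n_states,
    }


def recovery_experiment(seed: int, keep_rate: float = 0.1) -> dict[str, float]:
    """Train on the default fixture and score held-out recovery.

    Returns held-out label accuracy vs the planted truth plus the
    row-averaged Spearman correlation of the imputed and of the sparse
    matrices against the dense fixture matrix.
    """
    dense, sparse, truth = syn.default_fixture(seed=seed, keep_rate=keep_rate)
    cfg = TrainingConfig(seed=seed)
    models = ann.train_models(dense, keep_rate, truth, cfg)
    pred = ann.annotate_cell(models, sparse)
    held = np.concatenate([
        ~dense.row_grid.chrom_mask(models.manifest["train_chroms_odd"]),
        ~dense.col_grid.chrom_mask(models.manifest["train_chroms_even"]),
    ])
    acc = accuracy(pred.subset(held), truth.subset(held))
    imputed = ann.impute_matrix(models, sparse)
    dense_p = hm.to_probability(dense).probs
    sparse_p = hm.to_probability(sparse).probs
    r_imp = np.nanmean(
        [spearmanr(imputed.probs[i], dense_p[i]).statistic for i in range(len(dense_p))]
    )
    r_sparse = np.nanmean(
        [spearmanr(sparse_p[i], dense_p[i]).statistic for i in range(len(dense_p))]
    )
    return {
        "held_out_accuracy": float(acc),
        "spearman_imputed": float(r_imp),
        "spearman_sparse": float(r_sparse),
    }


def coverage_trend(seed: int, rates: tuple[float, ...] = SWEEP_RATES) -> pd.DataFrame:
    """Coverage-titration table on the default fixture (fixed models)."""
    dense, _, truth = syn.default_fixture(seed=seed)
    return coverage_sweep(dense, truth, list(rates), TrainingConfig(seed=seed))
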