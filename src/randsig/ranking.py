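"""Evaluation helpers for planted-driver recovery on synthetic studies."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import roc_auc_score

__all__ = ["RecoveryResult", "driver_recovery"]


@dataclass
class RecoveryResult:
    auroc: float
    fisher_p: float
    n_called: int
    n_drivers_called: int


def driver_recovery(
    scores: pd.DataFrame, calls: pd.DataFrame, drivers: list[str]
) -> RecoveryResult:
    """AUROC of the gene ranking for drivers-vs-rest plus the over-representation
    Fisher test of drivers among called genes.

    ``scores`` is the per-gene table (gene, raw_score, diffusion_score,
    permutation_score); ``calls`` the called-gene table.  The ranking key is
    (permutation score ascending, diffusion score descending, gene id), the
    order the caller uses.
    """
    driver_set = set(drivers)
    is_driver = scores["gene"].isin(driver_set).to_numpy()
    order = np.lexsort(
        (
            scores["gene"].to_numpy(),
            -scores["diffusion_score"].to_numpy(),
            scores["permutation_score"].to_numpy(),
        )
    )
    rank_pos = np.empty(len(order))
    rank_pos[order] = np.arange(len(order))
    auroc = float(roc_auc_score(is_driver, -rank_pos))
    called = scores["gene"].isin(set(calls["gene"])).to_numpy()
    table = [
        [int((called & is_driver).sum()), int((called & ~is_driver).sum())],
        [int((~called & is_driver).sum()), int((~called & ~is_driver).sum())],
    ]
    fisher_p = float(fisher_exact(table, alternative="greater")[1])
    return RecoveryResult(
        auroc=auroc,
        fisher_p=fisher_p,
        n_called=int(called.sum()),
        n_drivers_called=int((called & is_driver).sum()),
    )
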