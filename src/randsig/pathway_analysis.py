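"""Per-patient pathway scores and the phenotype-separation test.

Patients carry a binary phenotype label: ``N`` (good prognosis) and ``~N``
(poor prognosis).  For a pathway P and the set of called significant genes
SG, only the genes P_SG = P intersect SG contribute.  For each such gene the
phenotype means

    mu_N(g)  = mean expression of g over N patients
    mu_~N(g) = mean expression of g over ~N patients

anchor two per-patient scores, computed for every patient p of phenotype ~N:

    score_N(p)  = sum_{g in P_SG} e[g,p] * (e[g,p] - mu_N(g))**2
    score_~N(p) = sum_{g in P_SG} e[g,p] * (e[g,p] - mu_~N(g))**2

i.e. expression-weighted squared deviations from each phenotype's mean.  A
pathway whose genes behave differently in the two phenotypes produces
systematically different score_N and score_~N, which a paired t-test on the
per-patient differences detects.  The weights e[g,p] must be nonnegative; if
the cohort contains negative values (log-ratio data) the matrix is shifted by
its global minimum, with the shift logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import SurvivalCohort

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayScoreTable",
    "phenotype_means",
    "patient_pathway_scores",
    "pathway_separation_test",
]

GOOD, POOR = "N", "~N"


@dataclass
class PathwayScoreTable:
    pathway_name: str
    patient_ids: list[str]
    score_N: np.ndarray
    score_notN: np.ndarray
    n_genes: int
    p_value: float | None = None


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    good = labels == GOOD
    poor = labels == POOR
    if not (good | poor).all():
        raise ValueError(f"phenotype labels must be {GOOD!r} or {POOR!r}")
    if not good.any() or not poor.any():
        raise ValueError("both phenotypes must be non-empty")
    return labels


def phenotype_means(
    cohort: SurvivalCohort, phenotype_labels, genes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean expression in each phenotype, for the listed genes."""
    labels = _check_labels(phenotype_labels)
    rows = cohort.gene_rows(genes)
    x = cohort.expression[rows]
    return x[:, labels == GOOD].mean(axis=1), x[:, labels == POOR].mean(axis=1)


def patient_pathway_scores(
    cohort: SurvivalCohort,
    phenotype_labels,
    significant_genes: list[str],
    pathway: list[str],
    pathway_name: str = "",
    patients: str = "poor",
) -> PathwayScoreTable:
    """Both per-patient scores for one pathway.

    Scores are evaluated for the ~N (poor-prognosis) patients by default;
    ``patients="all"`` evaluates them for every patient, which makes the
    score pair exactly symmetric under a phenotype label swap.
    """
    labels = _check_labels(phenotype_labels)
    in_cohort = set(cohort.gene_ids)
    p_sg = sorted((set(pathway) & set(significant_genes)) & in_cohort)
    if not p_sg:
        raise ValueError(
            f"pathway {pathway_name or '<unnamed>'!r} shares no significant gene "
            "with the cohort"
        )
    x = cohort.expression[cohort.gene_rows(p_sg)]
    if x.min() < 0:
        shift = -float(cohort.expression.min())
        logger.warning(
            "expression contains negative values; shifting by %.4g for pathway weights",
            shift,
        )
        x = x + shift
    mu_n = x[:, labels == GOOD].mean(axis=1, keepdims=True)
    mu_not = x[:, labels == POOR].mean(axis=1, keepdims=True)
    if patients == "poor":
        poor_cols = labels == POOR
    elif patients == "all":
        poor_cols = np.ones(len(labels), dtype=bool)
    else:
        raise ValueError(f"unknown patients selection {patients!r}")
    e = x[:, poor_cols]
    score_n = (e * (e - mu_n) ** 2).sum(axis=0)
    score_not = (e * (e - mu_not) ** 2).sum(axis=0)
    patient_ids = [s for s, keep in zip(cohort.sample_ids, poor_cols) if keep]
    return PathwayScoreTable(
        pathway_name=pathway_name,
        patient_ids=patient_ids,
        score_N=score_n,
        score_notN=score_not,
        n_genes=len(p_sg),
    )


def pathway_separation_test(
    table: PathwayScoreTable, mode: str = "paired"
) -> float:
    """Two-sided t-test between score_N and score_~N.

    Default is the paired test on per-patient differences, since both scores
    are defined on the same ~N patients; ``mode="welch"`` runs the unpaired
    Welch test instead.  Degenerate cases: all differences zero -> p = 1;
    constant nonzero differences -> p = 0 with a logged warning (the paired t
    statistic is unbounded).
    """
    a, b = np.asarray(table.score_N, float), np.asarray(table.score_notN, float)
    if len(a) < 2:
        raise ValueError("need at least 2 patients for the separation test")
    if mode == "paired":
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0.0:
                table.p_value = 1.0
                return 1.0
            logger.warning(
                "pathway %s: constant nonzero score difference; t statistic degenerate",
                table.pathway_name,
            )
            table.p_value = 0.0
            return 0.0
        p = float(stats.ttest_rel(a, b).pvalue)
    elif mode == "welch":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table.p_value = p
    return p
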