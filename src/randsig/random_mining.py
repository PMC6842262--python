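"""Mining of significant random signatures.

For each template gene set (size template), a batch of random signatures of
identical size is drawn uniformly without replacement from the cohort's gene
universe.  Every random signature is scored with the nominal and empirical
p-value machinery of :mod:`randsig.signature_stats`, and the "significant
random signatures" are those passing both thresholds: empirical p-value at or
below ``empirical_threshold`` (default 0) and log10 nominal p-value at or
below ``log10_nominal_threshold`` (default -10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SurvivalCohort
from .signature_stats import SignificanceRecord, signature_significance

logger = logging.getLogger(__name__)

__all__ = [
    "RandomSignatureBatch",
    "generate_random_signatures",
    "evaluate_batch",
    "select_significant",
    "derive_seed",
]

#: defaults of the dual selection rule
EMPIRICAL_THRESHOLD = 0.0
LOG10_NOMINAL_THRESHOLD = -10.0


@dataclass
class RandomSignatureBatch:
    template_name: str
    size: int
    members: list[list[str]]
    seed: int
    records: list[SignificanceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.members:
            if len(set(m)) != self.size:
                raise ValueError(
                    f"batch member has {len(set(m))} distinct genes, expected {self.size}"
                )


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed below 2**31 from (master seed, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_random_signatures(
    universe: list[str],
    size: int,
    n: int,
    seed: int,
    template_name: str = "random",
) -> RandomSignatureBatch:
    """Draw ``n`` signatures of ``size`` genes uniformly without replacement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if size > len(universe):
        raise ValueError(f"size {size} exceeds universe of {len(universe)} genes")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    members = [list(rng.choice(universe, size=size, replace=False)) for _ in range(n)]
    return RandomSignatureBatch(
        template_name=template_name, size=size, members=members, seed=seed
    )


def evaluate_batch(
    batch: RandomSignatureBatch,
    cohort: SurvivalCohort,
    n_perm: int,
    seed: int,
    log_every: int = 200,
) -> RandomSignatureBatch:
    """Fill ``batch.records`` with nominal/adjusted/empirical p-values.

    Each member gets its own permutation seed derived from ``(seed, index)``
    so batches are reproducible independently of evaluation order.  A member
    with no gene present in the cohort is recorded as failed (p-values NaN),
    not fatal.
    """
    records: list[SignificanceRecord] = []
    for i, member in enumerate(batch.members):
        name = f"{batch.template_name}_r{i:04d}"
        try:
            rec = signature_significance(
                cohort, member, name=name, n_perm=n_perm, seed=derive_seed(seed, i)
            )
        except ValueError as exc:
            logger.warning("signature %s failed: %s", name, exc)
            rec = SignificanceRecord(
                signature_name=name,
                nominal_p=float("nan"),
                adjusted_p=float("nan"),
                empirical_p=float("nan"),
                n_perm=n_perm,
            )
        records.append(rec)
        if log_every and (i + 1) % log_every == 0:
            logger.info(
                "%s: evaluated %d/%d random signatures",
                batch.template_name,
                i + 1,
                len(batch.members),
            )
    batch.records = records
    return batch


def select_significant(
    batches: list[RandomSignatureBatch] | RandomSignatureBatch,
    empirical_threshold: float = EMPIRICAL_THRESHOLD,
    log10_nominal_threshold: float = LOG10_NOMINAL_THRESHOLD,
) -> list[tuple[str, list[str]]]:
    """Signatures passing both thresholds, as (name, gene list) pairs.

    A signature is selected when ``empirical_p <= empirical_threshold`` and
    ``log10(nominal_p) <= log10_nominal_threshold`` (both non-strict).  Failed
    records (NaN) never pass.
    """
    if isinstance(batches, RandomSignatureBatch):
        batches = [batches]
    nominal_cut = 10.0**log10_nominal_threshold
    selected: list[tuple[str, list[str]]] = []
    for batch in batches:
        if len(batch.records) != len(batch.members):
            raise ValueError(f"batch {batch.template_name!r} is not evaluated")
        for member, rec in zip(batch.members, batch.records):
            if np.isnan(rec.nominal_p):
                continue
            if rec.empirical_p <= empirical_threshold and rec.nominal_p <= nominal_cut:
                selected.append((rec.signature_name, member))
    return selected
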