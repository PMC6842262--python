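"""Readers, writers and identifier harmonization for the pipeline's file formats.

Expression matrices are TSV with genes in rows (first column = gene symbol,
header row = sample IDs).  Survival tables are three-column TSV
(``sample_id``, ``time``, ``event``).  Gene sets and pathways use the GMT
format.  Networks are STRING-style edge lists: two node columns followed by
one or more integer confidence columns on the 0-1000 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCohort",
    "GeneSetCollection",
    "WeightedNetwork",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "attach_survival",
    "read_gmt",
    "write_gmt",
    "read_string_edges",
    "write_string_edges",
    "harmonize_ids",
]


@dataclass
class SurvivalCohort:
    """Expression matrix plus per-sample survival outcome.

    ``expression`` is genes x samples; ``time`` is follow-up in a single
    consistent unit; ``event`` is 1 for an observed event, 0 for censoring.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    expression: np.ndarray
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if self.time.shape != (len(self.sample_ids),) or self.event.shape != (
                len(self.sample_ids),
            ):
                raise ValueError("time/event length does not match sample count")
            if np.any(self.time < 0):
                raise ValueError("negative survival time")
            if not np.isin(self.event, (0, 1)).all():
                raise ValueError("event indicator outside {0, 1}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self, genes: list[str]) -> np.ndarray:
        """Row indices of ``genes`` present in the cohort (absent genes skipped)."""
        return np.array([self._gene_index[g] for g in genes if g in self._gene_index], dtype=int)

    def submatrix(self, genes: list[str]) -> np.ndarray:
        return self.expression[self.gene_rows(genes)]


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures or pathways) as read from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class WeightedNetwork:
    """Undirected protein-protein interaction network with edge weights in [0, 1]."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, float]]) -> "WeightedNetwork":
        g = nx.Graph()
        for u, v, w in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if w < 0:
                raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
            g.add_edge(u, v, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


# ---------------------------------------------------------------------------
# expression


def read_expression(path) -> SurvivalCohort:
    """Read a genes-in-rows expression TSV into a :class:`SurvivalCohort` (no survival).

    Duplicate gene rows are collapsed by their mean (logged); duplicate sample
    columns are an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample IDs in {path}: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty or unparseable expression file: {path}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"expression file {path} has no sample columns")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric expression value in column {col!r}, row {bad.index[0]!r}"
        )
    if df.isna().any().any():
        raise ValueError(f"missing expression values in {path}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    return SurvivalCohort(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        expression=df.to_numpy(dtype=float),
    )


def write_expression(cohort: SurvivalCohort, path) -> None:
    pd.DataFrame(
        cohort.expression, index=cohort.gene_ids, columns=cohort.sample_ids
    ).to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# survival


def read_survival(path) -> pd.DataFrame:
    """Read a (sample_id, time, event) TSV; returns a sample-indexed frame."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival file {path} must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample IDs in survival file {path}")
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative survival time for sample {bad!r}")
    if not df["event"].isin((0, 1)).all():
        bad = df.loc[~df["event"].isin((0, 1)), "sample_id"].iloc[0]
        raise ValueError(f"event indicator outside {{0, 1}} for sample {bad!r}")
    return df.set_index("sample_id")


def write_survival(cohort: SurvivalCohort, path) -> None:
    pd.DataFrame(
        {"sample_id": cohort.sample_ids, "time": cohort.time, "event": cohort.event}
    ).to_csv(path, sep="\t", index=False)


def attach_survival(cohort: SurvivalCohort, survival: pd.DataFrame) -> SurvivalCohort:
    """Join survival records onto an expression-only cohort.

    Samples listed in the survival table but absent from the expression matrix
    are dropped with a logged count; expression samples without survival are an
    error (the cohort invariant forbids missing outcomes).
    """
    extra = set(survival.index) - set(cohort.sample_ids)
    if extra:
        logger.warning("dropping %d survival samples absent from expression", len(extra))
    missing = [s for s in cohort.sample_ids if s not in survival.index]
    if missing:
        raise ValueError(f"no survival record for expression samples: {missing[:5]}")
    sub = survival.loc[cohort.sample_ids]
    return SurvivalCohort(
        gene_ids=cohort.gene_ids,
        sample_ids=cohort.sample_ids,
        expression=cohort.expression,
        time=sub["time"].to_numpy(dtype=float),
        event=sub["event"].to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# GMT gene sets
#
# Parsed by hand: the format is one line per set (name TAB description TAB
# genes...) and we need line-number error reporting that library readers do
# not give.


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, ".")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# STRING-style network


def read_string_edges(
    path,
    score_column: str | None = None,
    min_score: float = 0.0,
    scale: float = 1000.0,
) -> WeightedNetwork:
    """Read a STRING-style TSV edge list into a :class:`WeightedNetwork`.

    ``score_column`` selects the confidence column (default: ``combined_score``
    if present, else the last column).  Scores are divided by ``scale``
    (STRING's 0-1000 convention) to give weights in [0, 1].  Rows below
    ``min_score`` (on the raw scale) are dropped, reciprocal duplicates are
    merged, and self-edges are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"network file {path} needs two node columns and a score column")
    node_a, node_b = df.columns[:2]
    if score_column is None:
        score_column = "combined_score" if "combined_score" in df.columns else df.columns[-1]
    scores = df[score_column].to_numpy(dtype=float)
    if (scores < 0).any() or (scores > scale).any():
        raise ValueError(f"scores in column {score_column!r} outside [0, {scale}]")
    g = nx.Graph()
    n_self = 0
    for u, v, s in zip(df[node_a].astype(str), df[node_b].astype(str), scores):
        if u == v:
            n_self += 1
            continue
        if s < min_score:
            continue
        w = s / scale
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    if n_self:
        logger.warning("dropped %d self-edges", n_self)
    return WeightedNetwork(g)


def write_string_edges(network: WeightedNetwork, path, scale: float = 1000.0) -> None:
    rows = [
        {"protein1": u, "protein2": v, "combined_score": int(round(w * scale))}
        for u, v, w in network.edge_list()
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# identifier harmonization


def _load_mapping(mapping) -> dict[str, str]:
    if isinstance(mapping, dict):
        items = list(mapping.items())
    else:
        df = pd.read_csv(mapping, sep="\t", header=0, dtype=str)
        items = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    out: dict[str, str] = {}
    for src, sym in items:
        if src in out and out[src] != sym:
            raise ValueError(f"ambiguous mapping: {src!r} -> {out[src]!r} and {sym!r}")
        out[src] = sym
    return out


def harmonize_ids(
    cohort: SurvivalCohort | None,
    sets: GeneSetCollection | None,
    network: WeightedNetwork | None,
    mapping,
) -> tuple[SurvivalCohort | None, GeneSetCollection | None, WeightedNetwork | None]:
    """Re-key all three objects to a shared gene-symbol namespace.

    ``mapping`` is a dict or a two-column TSV (source_id, gene_symbol).  IDs
    already equal to their symbol pass through; unmapped IDs are dropped from
    the object they appear in, with per-object logged counts.  A source ID
    mapped to two different symbols is an error.
    """
    table = _load_mapping(mapping)

    def rename(ident: str) -> str | None:
        return table.get(ident, ident if ident in symbol_universe else None)

    symbol_universe = set(table.values())

    new_cohort = cohort
    if cohort is not None:
        kept_rows, kept_names, seen = [], [], set()
        n_dropped = 0
        for i, g in enumerate(cohort.gene_ids):
            sym = rename(g)
            if sym is None or sym in seen:
                n_dropped += 1
                continue
            seen.add(sym)
            kept_rows.append(i)
            kept_names.append(sym)
        if n_dropped:
            logger.info("cohort: dropped %d unmapped/duplicate gene rows", n_dropped)
        new_cohort = SurvivalCohort(
            gene_ids=kept_names,
            sample_ids=cohort.sample_ids,
            expression=cohort.expression[kept_rows],
            time=cohort.time,
            event=cohort.event,
        )

    new_sets = sets
    if sets is not None:
        out_sets: dict[str, list[str]] = {}
        n_dropped = 0
        for name, genes in sets.items():
            mapped = []
            for g in genes:
                sym = rename(g)
                if sym is None:
                    n_dropped += 1
                else:
                    mapped.append(sym)
            deduped = list(dict.fromkeys(mapped))
            if deduped:
                out_sets[name] = deduped
        if n_dropped:
            logger.info("gene sets: dropped %d unmapped genes", n_dropped)
        new_sets = GeneSetCollection(sets=out_sets, descriptions=dict(sets.descriptions))

    new_network = network
    if network is not None:
        g = nx.Graph()
        n_dropped = 0
        for u, v, w in network.edge_list():
            su, sv = rename(u), rename(v)
            if su is None or sv is None:
                n_dropped += 1
                continue
            if su == sv:
                continue
            if g.has_edge(su, sv):
                g[su][sv]["weight"] = max(g[su][sv]["weight"], w)
            else:
                g.add_edge(su, sv, weight=w)
        if n_dropped:
            logger.info("network: dropped %d edges with unmapped endpoints", n_dropped)
        new_network = WeightedNetwork(g)

    return new_cohort, new_sets, new_network
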