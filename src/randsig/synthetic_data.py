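"""Synthetic cohorts, networks, and signature templates.

The generator emulates the statistical structure the pipeline assumes of a
breast-cancer style study:

* an expression matrix in which a planted **driver module** of genes shares a
  latent factor (equicorrelated at ``driver_correlation``) against an i.i.d.
  standard-normal background;
* survival outcomes whose log-hazard is proportional to each sample's latent
  driver-factor value (``hazard_effect``), with independent exponential
  censoring tuned to the requested censoring fraction — so random signatures
  that overlap the driver module carry outcome signal through their PC1, the
  premise the mining stage exploits;
* a scale-free (preferential-attachment) weighted interaction network over
  all genes, with the driver genes additionally wired into one connected
  module; edge confidences are uniform in ``weight_range``;
* size-matched signature templates standing in for a published signature
  collection.

Everything is reproducible from ``spec.seed`` through numpy's PCG64
generator.  Expression is shifted to be globally nonnegative so the weighted
pathway-score stage applies without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import networkx as nx

from .io_formats import GeneSetCollection, SurvivalCohort, WeightedNetwork

__all__ = ["SyntheticSpec", "generate_cohort", "generate_network", "generate_templates"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale cohort with a strong planted signal: 500
    genes, 200 samples, a 25-gene driver module at pairwise correlation 0.8,
    log-hazard 1.5 per unit of the driver factor, 30% censoring, a mean-degree
    4 scale-free network, and three size templates (8, 15, 30 genes).  The
    driver fraction and template sizes are set so a typical random signature
    contains at most one driver gene: selection then discriminates, picking a
    minority of signatures (those hitting the module several times) rather
    than nearly all of them, which is the regime the mining step assumes.
    """

    n_genes: int = 500
    n_samples: int = 200
    n_driver_genes: int = 25
    driver_correlation: float = 0.8
    hazard_effect: float = 1.5
    censoring_rate: float = 0.3
    network_model: str = "preferential_attachment"
    mean_degree: float = 4.0
    weight_range: tuple[float, float] = (0.4, 0.9)
    n_template_sets: int = 3
    template_sizes: tuple[int, ...] = (8, 15, 30)
    seed: int = 0
    baseline_hazard: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.n_driver_genes <= self.n_genes:
            raise ValueError("need 0 < n_driver_genes <= n_genes")
        if not 0.0 <= self.driver_correlation < 1.0:
            raise ValueError("driver_correlation must be in [0, 1)")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        lo, hi = self.weight_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("weight_range must satisfy 0 < lo <= hi <= 1")
        if self.network_model != "preferential_attachment":
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if len(self.template_sizes) != self.n_template_sets:
            raise ValueError("template_sizes length must equal n_template_sets")
        if max(self.template_sizes) > self.n_genes:
            raise ValueError("a template size exceeds the gene universe")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_range"] = list(self.weight_range)
        d["template_sizes"] = list(self.template_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "weight_range" in d:
            d["weight_range"] = tuple(d["weight_range"])
        if "template_sizes" in d:
            d["template_sizes"] = tuple(d["template_sizes"])
        return cls(**d)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _censoring_rate_for(lam_c: float, rates: np.ndarray) -> float:
    # P(C < T) when C ~ Exp(lam_c) and T ~ Exp(rate_j), averaged over samples
    return float(np.mean(lam_c / (lam_c + rates)))


def generate_cohort(spec: SyntheticSpec) -> tuple[SurvivalCohort, list[str]]:
    """Expression + survival cohort with planted drivers; returns the truth labels.

    Driver gene g has expression sqrt(rho)*f_j + sqrt(1-rho)*eps, sharing the
    latent factor f across the module, which yields pairwise correlation rho.
    Survival time for sample j is exponential with rate
    baseline_hazard * exp(hazard_effect * f_j); censoring is an independent
    exponential whose rate is solved by bisection so the expected censoring
    fraction equals ``censoring_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genes = _gene_names(spec.n_genes)
    drivers = sorted(rng.choice(genes, size=spec.n_driver_genes, replace=False).tolist())
    driver_rows = np.array([genes.index(g) for g in drivers])

    factor = rng.standard_normal(spec.n_samples)
    x = rng.standard_normal((spec.n_genes, spec.n_samples))
    rho = spec.driver_correlation
    x[driver_rows] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * x[driver_rows]

    rates = spec.baseline_hazard * np.exp(spec.hazard_effect * factor)
    t_event = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0.0:
        lo, hi = 1e-12, 1e12
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if _censoring_rate_for(mid, rates) < spec.censoring_rate:
                lo = mid
            else:
                hi = mid
        t_cens = rng.exponential(1.0 / mid, size=spec.n_samples)
    else:
        t_cens = np.full(spec.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    x -= x.min()  # nonnegative scale for the pathway-score weights
    cohort = SurvivalCohort(
        gene_ids=genes,
        sample_ids=[f"S{j:04d}" for j in range(1, spec.n_samples + 1)],
        expression=x,
        time=time,
        event=event,
    )
    return cohort, drivers


def generate_network(spec: SyntheticSpec, driver_genes: list[str]) -> WeightedNetwork:
    """Scale-free weighted network over all genes with a connected driver module.

    A Barabasi-Albert graph with attachment parameter round(mean_degree / 2)
    gives mean degree ~ mean_degree; its integer nodes are assigned to gene
    names in seeded random order so hubs are not systematically drivers.  The
    driver genes are then joined by a uniform random tree, guaranteeing they
    form one connected induced subgraph.  All edge weights are uniform in
    ``weight_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    genes = _gene_names(spec.n_genes)
    unknown = set(driver_genes) - set(genes)
    if unknown:
        raise ValueError(f"driver genes outside the universe: {sorted(unknown)[:5]}")
    m = max(1, int(round(spec.mean_degree / 2.0)))
    ba = nx.barabasi_albert_graph(spec.n_genes, m, seed=int(rng.integers(2**31)))
    assignment = list(rng.permutation(genes))
    g = nx.Graph()
    g.add_nodes_from(genes)
    for u, v in ba.edges:
        g.add_edge(assignment[u], assignment[v])
    order = list(rng.permutation(driver_genes))
    for i in range(1, len(order)):
        g.add_edge(order[i], order[int(rng.integers(i))])
    lo, hi = spec.weight_range
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(lo, hi))
    return WeightedNetwork(g)


def generate_templates(spec: SyntheticSpec, gene_universe: list[str]) -> GeneSetCollection:
    """Size-template gene sets sampled uniformly from the universe."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    sets, descriptions = {}, {}
    for k, size in enumerate(spec.template_sizes, start=1):
        if size > len(gene_universe):
            raise ValueError(f"template size {size} exceeds universe")
        name = f"template_{k:02d}_n{size}"
        sets[name] = sorted(rng.choice(gene_universe, size=size, replace=False).tolist())
        descriptions[name] = f"synthetic size template ({size} genes)"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
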