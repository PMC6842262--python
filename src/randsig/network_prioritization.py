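"""Network diffusion of occurrence scores and the permutation significance call.

Each gene receives a raw **occurrence score** S_i = the number of selected
significant random signatures that contain it.  The score vector is smoothed
over a weighted protein-protein interaction network with the heat (diffusion)
kernel

    K_beta = exp(-beta * L),      L = D - W  (weighted graph Laplacian),

so a gene's diffusion score combines its own score with those of its network
neighborhood; the bandwidth ``beta`` (default 0.3) controls how far scores
spread.  Because L has zero row sums and is symmetric, K_beta is symmetric,
nonnegative, and has unit column sums, so diffusion conserves total score
mass.

Note on the kernel sign: the heat kernel of Kondor and Lafferty is the matrix
exponential of the *negative* Laplacian.  An exponential of +L amplifies
high-degree structure without bound as the graph grows, so this package uses
exp(-beta*L) throughout.

Significance of a diffusion score is judged by a permutation null: the score
vector is randomly permuted across genes, re-diffused, and each gene's
**permutation score** is the fraction of replicates whose value at that
gene's position meets or exceeds the observed diffusion score.  Genes with a
permutation score below ``alpha`` (default 0.05) are called significant and
ranked by (permutation score ascending, diffusion score descending, gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .io_formats import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "DiffusionOperator",
    "GeneCall",
    "occurrence_scores",
    "build_laplacian",
    "diffusion_kernel",
    "diffuse",
    "permutation_scores",
    "call_significant_genes",
]

#: above this node count the kernel is applied as an action (expm_multiply)
#: instead of being formed densely by eigendecomposition
DENSE_LIMIT = 3000


@dataclass
class ScoreVector:
    """Per-gene scores with an explicit gene ordering."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("values length does not match gene_ids")


@dataclass
class DiffusionOperator:
    """The heat-kernel operator v -> exp(-beta L) v for a fixed gene ordering.

    For graphs up to :data:`DENSE_LIMIT` nodes the kernel matrix is formed
    explicitly by eigendecomposition of the symmetric Laplacian; beyond that
    only the sparse Laplacian is kept and the kernel is applied with
    ``scipy.sparse.linalg.expm_multiply``.
    """

    gene_ids: list[str]
    beta: float
    kernel: np.ndarray | None = None
    laplacian: sp.spmatrix | None = field(default=None, repr=False)

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Apply the kernel to a vector or to columns of a matrix."""
        v = np.asarray(v, dtype=float)
        if v.shape[0] != len(self.gene_ids):
            raise ValueError("vector length does not match operator gene ordering")
        if self.kernel is not None:
            return self.kernel @ v
        if self.beta == 0.0:
            return v.copy()
        return expm_multiply((-self.beta) * self.laplacian.tocsc(), v)

    def materialize(self) -> np.ndarray:
        if self.kernel is None:
            raise ValueError("operator is action-only; kernel matrix not formed")
        return self.kernel


@dataclass
class GeneCall:
    gene_id: str
    raw_score: float
    diffusion_score: float
    permutation_score: float
    rank: int


def occurrence_scores(
    selected_signatures: list[list[str]] | list[tuple[str, list[str]]],
    gene_ids: list[str],
) -> ScoreVector:
    """S_i = number of selected signatures that contain gene i."""
    index = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros(len(gene_ids))
    for sig in selected_signatures:
        genes = sig[1] if isinstance(sig, tuple) else sig
        for g in set(genes):
            i = index.get(g)
            if i is not None:
                values[i] += 1.0
    return ScoreVector(gene_ids=list(gene_ids), values=values)


def build_laplacian(network: WeightedNetwork, gene_ids: list[str]) -> sp.csr_matrix:
    """Weighted graph Laplacian L = D - W over the full gene ordering.

    Genes absent from the network are isolated (all-zero row/column), so the
    kernel acts as the identity on them and they stay eligible for calling.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    rows, cols, vals = [], [], []
    for u, v, w in network.edge_list():
        if w < 0:
            raise ValueError(f"negative edge weight on ({u!r}, {v!r})")
        iu, iv = index.get(u), index.get(v)
        if iu is None or iv is None:
            raise ValueError(f"network node outside the gene universe: {u!r}/{v!r}")
        rows += [iu, iv]
        cols += [iv, iu]
        vals += [w, w]
    n = len(gene_ids)
    adj = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(degrees) - adj).tocsr()


def diffusion_kernel(
    laplacian: sp.spmatrix | np.ndarray,
    beta: float,
    gene_ids: list[str] | None = None,
    dense_limit: int = DENSE_LIMIT,
) -> DiffusionOperator:
    """Heat-kernel operator exp(-beta L) for a symmetric zero-row-sum Laplacian."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    L = sp.csr_matrix(laplacian)
    n = L.shape[0]
    if gene_ids is None:
        gene_ids = [str(i) for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length does not match Laplacian size")
    if beta == 0.0:
        return DiffusionOperator(
            gene_ids=list(gene_ids), beta=0.0, kernel=np.eye(n)
        )
    if n <= dense_limit:
        dense = L.toarray()
        if not np.allclose(dense, dense.T, atol=1e-10):
            raise ValueError("Laplacian is not symmetric")
        eigval, eigvec = np.linalg.eigh(dense)
        kernel = (eigvec * np.exp(-beta * eigval)) @ eigvec.T
        # exact symmetry and clipping of tiny negative round-off
        kernel = (kernel + kernel.T) / 2.0
        np.clip(kernel, 0.0, None, out=kernel)
        return DiffusionOperator(gene_ids=list(gene_ids), beta=beta, kernel=kernel)
    logger.info("graph has %d nodes > %d; using action-based exponential", n, dense_limit)
    return DiffusionOperator(gene_ids=list(gene_ids), beta=beta, kernel=None, laplacian=L)


def diffuse(operator: DiffusionOperator, scores: ScoreVector) -> ScoreVector:
    """Diffusion scores S_beta = K_beta S.  Total mass is conserved."""
    if operator.gene_ids != scores.gene_ids:
        raise ValueError("operator and scores use different gene orderings")
    return ScoreVector(gene_ids=scores.gene_ids, values=operator.apply(scores.values))


def permutation_scores(
    operator: DiffusionOperator,
    scores: ScoreVector,
    n_perm: int,
    seed: int,
    null_mode: str = "as-printed",
    exhaustive: bool = False,
) -> np.ndarray:
    """Per-gene permutation scores of the diffusion result.

    The observed diffusion vector is S_beta = K S.  Each null replicate
    permutes a score vector uniformly at random across gene positions and
    re-applies the kernel; the permutation score of gene j is the fraction of
    replicates whose value at position j is greater than or equal to the
    observed S_beta(j).

    ``null_mode`` selects which vector is permuted: ``"as-printed"`` permutes
    the already-diffused S_beta (replicates are K perm(S_beta)), while
    ``"raw-scores"`` permutes the raw S (replicates are K perm(S)).  With
    ``exhaustive=True`` all n! permutations are enumerated instead of sampled
    (small n only, used by oracle tests).
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    if null_mode not in ("as-printed", "raw-scores"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    observed = operator.apply(scores.values)
    base = observed if null_mode == "as-printed" else np.asarray(scores.values, float)
    n = len(base)
    if exhaustive:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    counts = np.zeros(n)
    # exact ties (e.g. constant score vectors) must count as >=; a tiny
    # score-scaled tolerance keeps round-off from breaking them
    atol = 1e-9 * (1.0 + np.abs(observed))
    chunk = max(1, min(len(perms), int(2e7) // max(n, 1)))
    for lo in range(0, len(perms), chunk):
        block = base[perms[lo : lo + chunk]]  # (b, n) permuted vectors
        replicates = operator.apply(block.T).T  # K applied to each as a column
        counts += (replicates >= (observed - atol)[None, :]).sum(axis=0)
    return counts / len(perms)


def call_significant_genes(
    gene_ids: list[str],
    raw_scores: np.ndarray,
    diffusion_scores: np.ndarray,
    permutation_scores_: np.ndarray,
    alpha: float = 0.05,
) -> list[GeneCall]:
    """Genes with permutation score strictly below ``alpha``, ranked.

    Sort key: permutation score ascending, then diffusion score descending,
    then gene id ascending; ranks run 1..k.
    """
    keep = [
        (float(permutation_scores_[i]), -float(diffusion_scores[i]), gene_ids[i], i)
        for i in range(len(gene_ids))
        if permutation_scores_[i] < alpha
    ]
    keep.sort()
    return [
        GeneCall(
            gene_id=g,
            raw_score=float(raw_scores[i]),
            diffusion_score=float(diffusion_scores[i]),
            permutation_score=p,
            rank=r + 1,
        )
        for r, (p, _negd, g, i) in enumerate(keep)
    ]
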