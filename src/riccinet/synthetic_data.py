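"""Synthetic inputs for every stage of the pipeline.

Real gene networks come with a fixed interaction topology and two
phenotypes whose co-expression weights differ; the generators here emulate
exactly that design at desk scale: a fixed sparse topology (three named
random-graph families, or an explicit edge list), two-phenotype Gaussian
expression matrices whose correlation structure places a base correlation
on topology edges with planted shifts on chosen edges in the "tumor"
phenotype only, and small hand-checkable SIF / stoichiometric fixtures
for the topology builders.

Everything is bit-reproducible given the spec and its seed.  What the
Gaussian generator does *not* emulate: count marginals, batch effects, or
sample-level heterogeneity of real expression cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix, StoichiometricModel
from .exceptions import ParameterError, ValidationError
from .graph_model import WeightedNetwork

__all__ = [
    "SyntheticSpec",
    "generate_topology",
    "generate_expression",
    "generate_toy_sif",
    "generate_toy_stoichiometry",
    "unit_weight_network",
    "TOPOLOGY_MODELS",
    "ToySif",
    "ToyStoichiometry",
]

TOPOLOGY_MODELS = ("erdos-renyi", "ring-lattice", "preferential-attachment")

#: Eigenvalue floor for positive-definite repair of planted correlation
#: matrices, and the maximum entry shift the repair may introduce.
_EIG_FLOOR = 1e-6
_MAX_REPAIR_SHIFT = 0.1


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one two-phenotype synthetic data set.

    ``perturbed_edges`` maps an edge (gene-name pair) to an additive
    correlation shift applied in the tumor phenotype only.  ``noise_sd``
    scales the Gaussian marginals (it does not alter correlations).
    """

    n_genes: int = 20
    n_samples_per_phenotype: int = 100
    topology_model: str = "erdos-renyi"
    n_edges: int = 40
    base_correlation: float = 0.2
    perturbed_edges: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.base_correlation < 1:
            raise ParameterError(
                f"base correlation must lie in (-1, 1), got {self.base_correlation}"
            )
        for edge, shift in self.perturbed_edges.items():
            target = self.base_correlation + shift
            if not -1 < target < 1:
                raise ParameterError(
                    f"shifted correlation {target} on edge {edge} outside (-1, 1)"
                )


def generate_topology(
    model: str, n_nodes: int, n_edges: int, seed: int
) -> set[tuple[str, str]]:
    """A deterministic edge set from one of the named graph families.

    ``erdos-renyi`` draws exactly ``n_edges`` uniform edges; ``ring-lattice``
    connects each node to its ``k = 2 n_edges / n_nodes`` nearest ring
    neighbors (k must be an even integer); ``preferential-attachment``
    grows a Barabási–Albert graph and tops up (or trims) to exactly
    ``n_edges`` with seeded uniform choices.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 < n_edges <= max_edges:
        raise ParameterError(
            f"cannot place {n_edges} edges on {n_nodes} nodes (max {max_edges})"
        )
    names = _gene_names(n_nodes)
    if model == "erdos-renyi":
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(seed))
    elif model == "ring-lattice":
        k2 = 2 * n_edges
        if k2 % n_nodes != 0 or (k2 // n_nodes) % 2 != 0:
            raise ParameterError(
                "ring lattice needs 2*n_edges/n_nodes to be an even integer; "
                f"got n_nodes={n_nodes}, n_edges={n_edges}"
            )
        g = nx.watts_strogatz_graph(n_nodes, k2 // n_nodes, 0.0, seed=int(seed))
    elif model == "preferential-attachment":
        m_attach = max(1, round(n_edges / n_nodes))
        g = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(seed))
        rng = np.random.default_rng(seed)
        while g.number_of_edges() > n_edges:
            edges = sorted(g.edges)
            u, v = edges[rng.integers(len(edges))]
            g.remove_edge(u, v)
        while g.number_of_edges() < n_edges:
            u, v = rng.integers(n_nodes, size=2)
            if u != v and not g.has_edge(int(u), int(v)):
                g.add_edge(int(u), int(v))
    else:
        raise ParameterError(
            f"unknown topology model {model!r}; choose from {TOPOLOGY_MODELS}"
        )
    edges = set()
    for u, v in g.edges:
        a, b = names[u], names[v]
        edges.add((a, b) if a < b else (b, a))
    return edges


def unit_weight_network(edges, nodes: Sequence[str] = ()) -> WeightedNetwork:
    """A WeightedNetwork with weight 1 on every given edge."""
    return WeightedNetwork(((u, v, 1.0) for u, v in edges), nodes=nodes)


def _planted_correlation(
    spec: SyntheticSpec, edges: Sequence[tuple[str, str]], tumor: bool
) -> np.ndarray:
    names = _gene_names(spec.n_genes)
    idx = {g: i for i, g in enumerate(names)}
    corr = np.eye(spec.n_genes)
    perturbed = {
        tuple(sorted((str(a), str(b)))): s for (a, b), s in spec.perturbed_edges.items()
    }
    for u, v in edges:
        rho = spec.base_correlation
        if tumor and (u, v) in perturbed:
            rho += perturbed[(u, v)]
        corr[idx[u], idx[v]] = corr[idx[v], idx[u]] = rho
    return corr


def _repair_positive_definite(corr: np.ndarray) -> np.ndarray:
    """Nearest-in-spirit PD repair: clip eigenvalues, renormalize diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= _EIG_FLOOR:
        return corr
    vals = np.clip(vals, _EIG_FLOOR, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, set[tuple[str, str]], dict]:
    """Two-phenotype Gaussian expression data with planted edge correlations.

    Returns ``(expression, topology, ground_truth)``.  Samples are drawn
    from multivariate Gaussians whose correlation matrices carry
    ``base_correlation`` on every topology edge, with ``perturbed_edges``
    shifted in the tumor phenotype only; matrices are repaired to positive
    definite by eigenvalue clipping and diagonal renormalization.  The
    ground-truth sidecar stores the *realized* (post-repair) per-edge
    correlations for honest parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    topo_seed = int(rng.integers(2**31 - 1))
    edges = sorted(
        generate_topology(spec.topology_model, spec.n_genes, spec.n_edges, topo_seed)
    )
    edge_set = set(edges)
    for e in spec.perturbed_edges:
        key = tuple(sorted((str(e[0]), str(e[1]))))
        if key not in edge_set:
            raise ValidationError(f"perturbed edge {key} not in generated topology")

    names = _gene_names(spec.n_genes)
    idx = {g: i for i, g in enumerate(names)}
    ground_truth: dict = {"edges": {}, "seed": spec.seed, "topology_model": spec.topology_model}
    blocks = {}
    for label, tumor in (("normal", False), ("tumor", True)):
        corr = _repair_positive_definite(_planted_correlation(spec, edges, tumor))
        planted = _planted_correlation(spec, edges, tumor)
        shift = np.abs(corr - planted).max()
        if shift > _MAX_REPAIR_SHIFT:
            raise ValidationError(
                f"positive-definite repair moved a correlation by {shift:.3f} "
                f"(> {_MAX_REPAIR_SHIFT}); the planted structure is infeasible"
            )
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((spec.n_genes, spec.n_samples_per_phenotype))
        blocks[label] = spec.noise_sd * (chol @ z)
        for u, v in edges:
            ground_truth["edges"].setdefault(f"{u}|{v}", {})[label] = {
                "planted": float(planted[idx[u], idx[v]]),
                "realized": float(corr[idx[u], idx[v]]),
            }

    n = spec.n_samples_per_phenotype
    width = max(3, len(str(n)))
    samples = [f"N{i:0{width}d}" for i in range(n)] + [f"T{i:0{width}d}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([blocks["normal"], blocks["tumor"]]), index=names, columns=samples
    )
    phenotype = pd.Series(
        ["normal"] * n + ["tumor"] * n, index=samples, name="phenotype"
    )
    return ExpressionMatrix(values, phenotype), edge_set, ground_truth


# -- toy fixtures for the topology builders ---------------------------------


@dataclass(frozen=True)
class ToySif:
    """SIF rows with a known filtered edge set for exact builder tests."""

    rows: tuple[str, ...]
    gene_set: frozenset[str]
    keep_type: str
    expected_edges: frozenset[tuple[str, str]]


def generate_toy_sif(
    n_rows: int = 12,
    types: Sequence[str] = ("neighborhood-of", "controls-expression-of"),
    seed: int = 0,
) -> ToySif:
    """SIF fixture mixing keep-type in-set edges with distractors.

    Roughly half the rows are ``types[0]`` edges inside the designated gene
    set (including an injected duplicate and a reversed duplicate); the
    rest are other interaction types or involve out-of-set genes.
    """
    if len(types) < 2:
        raise ParameterError("need at least two interaction types")
    rng = np.random.default_rng(seed)
    keep_type = types[0]
    in_genes = [f"IN{i:02d}" for i in range(8)]
    out_genes = [f"OUT{i:02d}" for i in range(4)]
    rows: list[str] = []
    expected: set[tuple[str, str]] = set()
    for k in range(n_rows):
        kind = k % 4
        if kind in (0, 1):  # keep-type edge inside the gene set
            u, v = rng.choice(in_genes, size=2, replace=False)
            rows.append(f"{u}\t{keep_type}\t{v}")
            expected.add((u, v) if u < v else (v, u))
            if kind == 1:  # reversed duplicate: must collapse
                rows.append(f"{v}\t{keep_type}\t{u}")
        elif kind == 2:  # wrong interaction type
            u, v = rng.choice(in_genes, size=2, replace=False)
            other = types[1 + int(rng.integers(len(types) - 1))]
            rows.append(f"{u}\t{other}\t{v}")
        else:  # endpoint outside the gene set
            u = in_genes[int(rng.integers(len(in_genes)))]
            v = out_genes[int(rng.integers(len(out_genes)))]
            rows.append(f"{u}\t{keep_type}\t{v}")
    return ToySif(
        rows=tuple(rows),
        gene_set=frozenset(in_genes),
        keep_type=keep_type,
        expected_edges=frozenset(expected),
    )


@dataclass(frozen=True)
class ToyStoichiometry:
    """Stoichiometric fixture with an independently derived expected adjacency."""

    model: StoichiometricModel
    expected_edges: frozenset[tuple[str, str]]  # after cofactor pruning, no size cap


def generate_toy_stoichiometry(
    n_metabolites: int = 6,
    n_reactions: int = 5,
    n_genes: int = 6,
    n_cofactors: int = 1,
    seed: int = 0,
) -> ToyStoichiometry:
    """Random sparse S and R matrices plus a set-logic oracle adjacency.

    The expected edge set is computed without matrix algebra: two genes are
    adjacent iff some non-cofactor metabolite touches a reaction of each.
    """
    rng = np.random.default_rng(seed)
    mets = [f"M{i:02d}" for i in range(n_metabolites)]
    rxns = [f"R{i:02d}" for i in range(n_reactions)]
    genes = [f"G{i:02d}" for i in range(n_genes)]
    cofactors = mets[:n_cofactors]
    # each reaction touches 2-3 metabolites with +-1/+-2 coefficients
    s = np.zeros((n_metabolites, n_reactions))
    for j in range(n_reactions):
        chosen = rng.choice(n_metabolites, size=int(rng.integers(2, 4)), replace=False)
        for i in chosen:
            s[i, j] = rng.choice([-2, -1, 1, 2])
    # each reaction maps to 1-2 genes
    r = np.zeros((n_reactions, n_genes))
    for j in range(n_reactions):
        for g in rng.choice(n_genes, size=int(rng.integers(1, 3)), replace=False):
            r[j, g] = 1
    model = StoichiometricModel(
        pd.DataFrame(s, index=mets, columns=rxns),
        pd.DataFrame(r, index=rxns, columns=genes),
        cofactors=list(cofactors),
    )
    # set-logic oracle
    met_genes: dict[str, set[str]] = {m: set() for m in mets}
    for i, m in enumerate(mets):
        if m in cofactors:
            continue
        for j, rx in enumerate(rxns):
            if s[i, j] != 0:
                for g_i, g in enumerate(genes):
                    if r[j, g_i] != 0:
                        met_genes[m].add(g)
    expected: set[tuple[str, str]] = set()
    for shared in met_genes.values():
        for u in shared:
            for v in shared:
                if u < v:
                    expected.add((u, v))
    return ToyStoichiometry(model=model, expected_edges=frozenset(expected))
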