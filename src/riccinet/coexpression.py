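"""From expression data to weighted networks, and back to statistics.

A fixed gene–gene topology (from pathway interaction files or a metabolic
reconstruction) is decorated with phenotype-specific weights: for each edge
the Spearman rank correlation ``rho`` across that phenotype's samples is
mapped to ``w = (1 + rho)/2`` in [0, 1], so the same topology carries a
"normal" and a "tumor" random walk that differ only in diffusivity.

Differential co-expression of an edge standardizes the change in
correlation between phenotypes via the Fisher z-transform:

    dC = (z_T - z_N) / sqrt(1/(N_T - 3) + 1/(N_N - 3))

with ``z = atanh(c)`` and ``N_T``, ``N_N`` the phenotype sample counts.
Per-gene differential expression sums these edge values over the gene's
incident topology edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ParameterError,
    SampleSizeError,
    UnknownNodeError,
    ValidationError,
)
from .graph_model import WeightedNetwork

__all__ = [
    "ExpressionMatrix",
    "StoichiometricModel",
    "read_expression",
    "spearman_weights",
    "edge_spearman",
    "fisher_z",
    "differential_coexpression",
    "differential_expression_gene",
    "sif_topology",
    "read_stoichiometric_model",
    "stoichiometric_topology",
]

logger = logging.getLogger(__name__)

FISHER_CLIP = 1.0 - 1e-7

#: Spearman rho is floored just above -1 when converted to a walk weight so
#: that perfectly anticorrelated edges keep a (vanishing) positive weight
#: and the fixed topology survives in both phenotype networks.
RHO_FLOOR = -1.0 + 1e-7


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a phenotype label per sample."""

    values: pd.DataFrame  # genes (rows) x samples (columns)
    phenotype: pd.Series  # sample -> label

    def __post_init__(self) -> None:
        self.values.index = self.values.index.map(str)
        self.values.columns = self.values.columns.map(str)
        self.phenotype.index = self.phenotype.index.map(str)
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.phenotype.index)
        if missing:
            raise ValidationError(
                f"samples without phenotype label: {sorted(missing)[:5]}"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.phenotype[list(self.values.columns)])))

    def phenotype_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.phenotype[s] == label]

    def submatrix(self, label: str) -> pd.DataFrame:
        return self.values[self.phenotype_samples(label)]


def read_expression(expr_path, phenotype_path, impute: str | None = None) -> ExpressionMatrix:
    """Load a genes x samples CSV and a two-column (sample, label) map.

    ``impute="gene_mean"`` replaces missing values by the row mean; the
    default refuses matrices with missing entries.
    """
    values = pd.read_csv(expr_path, index_col=0)
    if impute == "gene_mean":
        values = values.apply(lambda row: row.fillna(row.mean()), axis=1)
    elif impute is not None:
        raise ParameterError(f"unknown imputation mode {impute!r}")
    pheno = pd.read_csv(phenotype_path, index_col=0).iloc[:, 0]
    return ExpressionMatrix(values, pheno)


def _normalize_topology(topology: Iterable) -> list[tuple[str, str]]:
    edges = set()
    for pair in topology:
        u, v = pair[0], pair[1]
        u, v = str(u), str(v)
        if u == v:
            continue
        edges.add((u, v) if u < v else (v, u))
    return sorted(edges)


def edge_spearman(
    expr: ExpressionMatrix,
    phenotype: str,
    topology: Iterable,
    strict: bool = False,
) -> dict[tuple[str, str], float]:
    """Per-edge Spearman correlation within one phenotype's samples.

    Ties get average ranks.  A constant gene makes the correlation
    undefined; by default the edge gets ``rho = 0`` with a warning
    (``strict=True`` raises instead).
    """
    samples = expr.phenotype_samples(phenotype)
    if len(samples) < 4:
        raise SampleSizeError(
            f"phenotype {phenotype!r} has {len(samples)} samples; need >= 4"
        )
    sub = expr.values[samples]
    edges = _normalize_topology(topology)
    genes_needed = {g for e in edges for g in e}
    missing = genes_needed - set(expr.genes)
    if missing:
        raise UnknownNodeError(
            f"topology genes absent from expression matrix: {sorted(missing)[:5]}"
        )
    # rank once per gene, then correlate ranks (Pearson on ranks == Spearman)
    ranks = sub.loc[sorted(genes_needed)].rank(axis=1, method="average")
    arr = ranks.to_numpy()
    idx = {g: i for i, g in enumerate(ranks.index)}
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    out: dict[tuple[str, str], float] = {}
    for u, v in edges:
        i, j = idx[u], idx[v]
        denom = norms[i] * norms[j]
        if denom == 0:
            if strict:
                raise ValidationError(
                    f"constant gene makes Spearman undefined on edge ({u!r}, {v!r})"
                )
            logger.warning(
                "undefined Spearman on edge (%s, %s): constant gene; using rho = 0",
                u,
                v,
            )
            rho = 0.0
        else:
            rho = float(np.dot(centered[i], centered[j]) / denom)
        out[(u, v)] = rho
    return out


def spearman_weights(
    expr: ExpressionMatrix,
    phenotype: str,
    topology: Iterable,
    strict: bool = False,
) -> WeightedNetwork:
    """Weighted network for one phenotype over the fixed topology.

    Each topology edge carries ``w = (1 + rho)/2`` with ``rho`` the
    phenotype's Spearman correlation (floored just above -1 so the edge is
    never dropped); non-edges keep weight 0.
    """
    rhos = edge_spearman(expr, phenotype, topology, strict=strict)
    nodes = sorted({g for e in rhos for g in e})
    edges = []
    for (u, v), rho in rhos.items():
        if rho < RHO_FLOOR:
            logger.warning(
                "edge (%s, %s): rho = %s floored to keep the topology edge", u, v, rho
            )
            rho = RHO_FLOOR
        edges.append((u, v, (1.0 + rho) / 2.0))
    return WeightedNetwork(edges, nodes=nodes)


def fisher_z(c: float) -> float:
    """Variance-stabilizing transform ``z = atanh(c) = 0.5 log((1+c)/(1-c))``.

    Correlations at or beyond +-1 are clipped to ``+-(1 - 1e-7)`` with a
    warning (rank correlations of exactly +-1 do occur in small data sets).
    """
    c = float(c)
    if abs(c) >= 1.0:
        logger.warning("fisher_z: |c| >= 1 (c = %s); clipping", c)
        c = math.copysign(FISHER_CLIP, c)
    return math.atanh(c)


def differential_coexpression(c_tumor: float, c_normal: float, n_tumor: int, n_normal: int) -> float:
    """Standardized change in correlation between two phenotypes.

    ``(z_T - z_N) / sqrt(1/(N_T - 3) + 1/(N_N - 3))`` with ``z`` the Fisher
    transform of the raw (untransformed) correlations.
    """
    if n_tumor <= 3 or n_normal <= 3:
        raise SampleSizeError(
            f"Fisher variance needs more than 3 samples per phenotype "
            f"(got {n_tumor}, {n_normal})"
        )
    se = math.sqrt(1.0 / (n_tumor - 3) + 1.0 / (n_normal - 3))
    return (fisher_z(c_tumor) - fisher_z(c_normal)) / se


def differential_expression_gene(
    diff_table: dict[tuple[str, str], float], topology: Iterable, gene
) -> float:
    """Sum of edge differential co-expression values incident to ``gene``."""
    gene = str(gene)
    edges = _normalize_topology(topology)
    genes = {g for e in edges for g in e}
    if gene not in genes:
        raise UnknownNodeError(f"gene {gene!r} not present in topology")
    total = 0.0
    for u, v in edges:
        if gene in (u, v):
            key = (u, v)
            if key in diff_table:
                total += diff_table[key]
    return total


# -- topology builders -------------------------------------------------------


def sif_topology(sif, keep_type: str, gene_set: Iterable) -> set[tuple[str, str]]:
    """Undirected edge set from Simple Interaction Format rows.

    Keeps only rows whose interaction type equals ``keep_type`` and whose
    *both* endpoints lie in ``gene_set``; reversed duplicates collapse to
    one undirected edge and self-loops are dropped.

    ``sif`` may be a path or an iterable of lines/row-tuples.
    """
    genes = {str(g) for g in gene_set}
    if isinstance(sif, (str, Path)):
        with open(sif) as fh:
            lines = fh.readlines()
    else:
        lines = list(sif)
    edges: set[tuple[str, str]] = set()
    for lineno, row in enumerate(lines, start=1):
        if isinstance(row, str):
            line = row.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
        else:
            parts = [str(p) for p in row]
        if len(parts) != 3:
            raise ValidationError(
                f"SIF line {lineno}: expected 3 columns, got {len(parts)}"
            )
        src, itype, dst = (p.strip() for p in parts)
        if itype != keep_type or src == dst:
            continue
        if src not in genes or dst not in genes:
            continue
        edges.add((src, dst) if src < dst else (dst, src))
    return edges


@dataclass
class StoichiometricModel:
    """Stoichiometric matrix S (metabolites x reactions), reaction-to-gene
    incidence R (reactions x genes), and the cofactor metabolites to prune."""

    S: pd.DataFrame
    R: pd.DataFrame
    cofactors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S.index = self.S.index.map(str)
        self.S.columns = self.S.columns.map(str)
        self.R.index = self.R.index.map(str)
        self.R.columns = self.R.columns.map(str)
        self.cofactors = [str(c) for c in self.cofactors]
        if list(self.S.columns) != list(self.R.index):
            raise ValidationError(
                "stoichiometric model not conformable: S columns (reactions) "
                "must equal R rows"
            )


def read_stoichiometric_model(s_path, r_path, cofactor_path=None) -> StoichiometricModel:
    """Load S and R CSVs (row ids in the first column) plus an optional
    one-cofactor-per-line list."""
    s = pd.read_csv(s_path, index_col=0)
    r = pd.read_csv(r_path, index_col=0)
    cofactors: list[str] = []
    if cofactor_path is not None:
        with open(cofactor_path) as fh:
            cofactors = [line.strip() for line in fh if line.strip()]
    return StoichiometricModel(s, r, cofactors)


def stoichiometric_topology(
    model: StoichiometricModel, max_reaction_size: int | None = None
) -> set[tuple[str, str]]:
    """Gene–gene adjacency from shared metabolites.

    Cofactor metabolites are removed from S; reactions touching more than
    ``max_reaction_size`` distinct remaining metabolites are optionally
    dropped; then ``MG = S_P x R`` links metabolites to genes through
    reactions and ``A = MG^T x MG`` counts shared metabolites per gene
    pair.  Matrices are binarized before and after each product so
    stoichiometric coefficients and gene multiplicities act only as
    presence/absence; the diagonal is zeroed and off-diagonal nonzeros are
    the returned undirected edges.
    """
    s = model.S.drop(index=[c for c in model.cofactors if c in model.S.index])
    sp = (s.to_numpy() != 0).astype(int)
    if max_reaction_size is not None:
        keep = sp.sum(axis=0) <= max_reaction_size
    else:
        keep = np.ones(sp.shape[1], dtype=bool)
    sp = sp[:, keep]
    r = (model.R.to_numpy() != 0).astype(int)[keep, :]
    mg = ((sp @ r) != 0).astype(int)  # metabolites x genes
    a = ((mg.T @ mg) != 0).astype(int)
    np.fill_diagonal(a, 0)
    genes = [str(g) for g in model.R.columns]
    edges = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if a[i, j]:
                u, v = genes[i], genes[j]
                edges.add((u, v) if u < v else (v, u))
    return edges
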