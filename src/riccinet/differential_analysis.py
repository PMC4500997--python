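"""Comparing two networks that share a topology.

Given per-pair curvature (or per-node entropy) tables computed for two
phenotypes on the same topology, this module ranks pairs by the change
``tumor - normal``, summarizes the distribution shift (difference of
means, tail means at several fractions), and tests the shift with the
paired one-tailed Wilcoxon signed-rank test.  ``run_differential_pipeline``
composes the whole workflow from an expression matrix and a topology into
a written report bundle.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .coexpression import (
    ExpressionMatrix,
    differential_coexpression,
    differential_expression_gene,
    edge_spearman,
    spearman_weights,
)
from .curvature import (
    CurvatureTable,
    curvature_all_pairs,
    network_average_curvature,
    scalar_curvature_normalized,
    scalar_curvature_unnormalized,
)
from .entropy import entropy_all_nodes
from .exceptions import (
    AlignmentError,
    ParameterError,
    PipelineError,
    ValidationError,
)

__all__ = [
    "DeltaTable",
    "delta_table",
    "top_bottom",
    "distribution_summary",
    "wilcoxon_signed_rank_paired",
    "PipelineConfig",
    "DifferentialReport",
    "run_differential_pipeline",
]

logger = logging.getLogger(__name__)

#: Tail-length schedule used in the distribution summaries.
DEFAULT_TAIL_FRACTIONS = (0.001, 0.005, 0.01, 0.03, 0.05)


@dataclass
class DeltaTable:
    """Per-key differences between two aligned tables.

    ``data`` is indexed by the shared keys (pair tuples or node ids) with
    columns ``value_tumor``, ``value_normal``, ``delta`` and ``rank``
    (descending delta, ties broken lexicographically by key) plus any
    companion columns attached later.
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def with_companion(self, name: str, values: pd.Series) -> "DeltaTable":
        out = self.data.copy()
        out[name] = values.reindex(out.index)
        return DeltaTable(out)

    def sorted(self) -> pd.DataFrame:
        return self.data.sort_values("rank")


def _as_series(table) -> pd.Series:
    if isinstance(table, CurvatureTable):
        return table.pair_series()
    if isinstance(table, pd.Series):
        return table
    if isinstance(table, pd.DataFrame) and "node" in table.columns:
        cols = [c for c in table.columns if c != "node"]
        if len(cols) == 1:
            return table.set_index("node")[cols[0]]
    raise ParameterError(
        "expected a CurvatureTable, a Series, or a single-value node DataFrame"
    )


def delta_table(tumor, normal) -> DeltaTable:
    """Tumor-minus-normal differences, ranked descending.

    Both inputs must carry identical keys; a mismatch raises
    :class:`AlignmentError` naming the offending keys.
    """
    t, n = _as_series(tumor), _as_series(normal)
    t_keys, n_keys = set(t.index), set(n.index)
    if t_keys != n_keys:
        offenders = sorted(map(str, t_keys.symmetric_difference(n_keys)))
        raise AlignmentError(
            f"tables do not share keys; {len(offenders)} offender(s), "
            f"first: {offenders[:5]}"
        )
    df = pd.DataFrame({"value_tumor": t, "value_normal": n.reindex(t.index)})
    df["delta"] = df["value_tumor"] - df["value_normal"]
    df = df.sort_index()  # lexicographic tie-break baseline
    order = np.argsort(-df["delta"].to_numpy(), kind="stable")
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return DeltaTable(df)


def top_bottom(delta: DeltaTable, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First and last ``k`` rows of the descending delta ranking."""
    if k > len(delta):
        raise ParameterError(f"k = {k} exceeds table size {len(delta)}")
    ordered = delta.sorted()
    return ordered.head(k), ordered.tail(k)


def _tail_means(values: np.ndarray, q: float) -> tuple[float, float]:
    n = len(values)
    m = math.ceil(q * n)
    s = np.sort(values)
    return float(s[:m].mean()), float(s[-m:].mean())


def distribution_summary(
    delta: DeltaTable,
    tail_fractions: Sequence[float] = DEFAULT_TAIL_FRACTIONS,
    tail_mode: str = "distribution",
) -> dict:
    """Distribution-shift summary between the two aligned value sets.

    Reports the difference of means (and the identical-for-aligned-tables
    mean paired difference), and for each tail fraction ``q`` the
    tumor-minus-normal difference of the mean over each distribution's
    lowest / highest ``ceil(q n)`` values.  ``tail_mode="paired"`` instead
    takes tails of the paired differences themselves.
    """
    if len(delta) == 0:
        raise ValidationError("empty delta table")
    for q in tail_fractions:
        if not 0 < q <= 0.5:
            raise ParameterError(f"tail fraction {q} outside (0, 0.5]")
    if tail_mode not in ("distribution", "paired"):
        raise ParameterError(f"unknown tail_mode {tail_mode!r}")
    t = delta.data["value_tumor"].to_numpy(dtype=float)
    n = delta.data["value_normal"].to_numpy(dtype=float)
    d = delta.data["delta"].to_numpy(dtype=float)
    out = {
        "delta_average": float(t.mean() - n.mean()),
        "mean_paired_difference": float(d.mean()),
        "tails": {},
    }
    for q in tail_fractions:
        if tail_mode == "distribution":
            t_lo, t_hi = _tail_means(t, q)
            n_lo, n_hi = _tail_means(n, q)
            left, right = t_lo - n_lo, t_hi - n_hi
        else:
            left, right = _tail_means(d, q)
        out["tails"][f"{q:g}"] = {"left": left, "right": right}
    return out


# -- paired Wilcoxon signed-rank test ---------------------------------------


def _exact_sf(doubled_ranks: np.ndarray, doubled_obs: int) -> float:
    """P(W+ >= obs) under the null where each sign is a fair coin.

    Works on doubled ranks (integers even with midrank ties) via a
    subset-sum convolution over the 2^n equally likely sign assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(doubled_ranks)
    return float(counts[doubled_obs:].sum() / 2.0**n)


def wilcoxon_signed_rank_paired(
    tumor: Iterable[float],
    normal: Iterable[float],
    alternative: str = "greater",
) -> float:
    """One-tailed paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (classic Wilcoxon convention) and tied
    absolute differences get average ranks.  The null distribution is exact
    (full convolution over sign assignments) for up to 25 nonzero pairs and
    a normal approximation with continuity and tie corrections beyond.  If
    every difference is zero the test is degenerate: p = 1 with a warning.
    """
    if alternative not in ("greater", "less"):
        raise ParameterError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    t = np.asarray(list(tumor), dtype=float)
    n = np.asarray(list(normal), dtype=float)
    if t.shape != n.shape:
        raise AlignmentError(f"unpaired inputs: {t.shape} vs {n.shape}")
    d = t - n
    if alternative == "less":
        d = -d
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    m = len(d)
    if m <= 25:
        doubled = np.rint(2 * ranks).astype(int)
        doubled_obs = int(np.rint(2 * w_plus))
        return _exact_sf(doubled, doubled_obs)
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


# -- end-to-end pipeline ----------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration for the differential pipeline."""

    tumor_label: str = "tumor"
    normal_label: str = "normal"
    scope: str = "adjacent"
    tail_fractions: tuple[float, ...] = DEFAULT_TAIL_FRACTIONS
    top_k: int = 10
    strict_spearman: bool = False
    seed: int | None = None


@dataclass
class DifferentialReport:
    """All artifacts of one two-phenotype differential run."""

    config: PipelineConfig
    curvature_tumor: CurvatureTable
    curvature_normal: CurvatureTable
    entropy_tumor: pd.DataFrame
    entropy_normal: pd.DataFrame
    delta_curvature: DeltaTable  # with diff_coexpression companion
    delta_nodal: pd.DataFrame
    gene_differential_expression: pd.Series
    summary: dict
    top: pd.DataFrame = field(default=None)
    bottom: pd.DataFrame = field(default=None)

    def write(self, outdir) -> None:
        """Write the TSV tables, JSON summary and manifest to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curvature_tumor.to_tsv(outdir / "curvature_tumor.tsv")
        self.curvature_normal.to_tsv(outdir / "curvature_normal.tsv")
        for name, table in (
            ("entropy_tumor.tsv", self.entropy_tumor),
            ("entropy_normal.tsv", self.entropy_normal),
        ):
            out = table.copy()
            for col in out.columns[1:]:
                out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
            out.to_csv(outdir / name, sep="\t", index=False)
        _write_delta_ranking(self.delta_curvature, outdir / "delta_curvature.tsv")
        nod = self.delta_nodal.copy()
        for col in nod.columns[1:]:
            nod[col] = nod[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
        nod.to_csv(outdir / "delta_nodal.tsv", sep="\t", index=False)
        gde = self.gene_differential_expression.map(lambda v: f"{v:.6f}")
        gde.rename("diff_expression").to_csv(
            outdir / "gene_differential_expression.tsv", sep="\t",
            index_label="gene",
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest = {
            "config": asdict(self.config),
            "version": __version__,
            "files": sorted(
                p.name for p in outdir.iterdir() if p.name != "manifest.json"
            ),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_delta_ranking(delta: DeltaTable, path) -> None:
    """Ranked pair table: rank, delta kappa, differential co-expression,
    gene X, gene Y."""
    ordered = delta.sorted().reset_index(names=["gene_x", "gene_y"])
    cols = {"rank": ordered["rank"]}
    cols["delta_kappa"] = ordered["delta"].map(lambda v: f"{v:.6f}")
    if "diff_coexpression" in ordered:
        cols["diff_coexpression"] = ordered["diff_coexpression"].map(
            lambda v: f"{v:.6f}"
        )
    cols["gene_x"] = ordered["gene_x"]
    cols["gene_y"] = ordered["gene_y"]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_differential_pipeline(
    expr: ExpressionMatrix, topology: Iterable, config: PipelineConfig | None = None
) -> DifferentialReport:
    """Full two-phenotype differential analysis over a fixed topology.

    Builds both phenotype networks, computes curvature and entropy tables,
    per-pair delta rankings with differential co-expression companions,
    distribution summaries and Wilcoxon p-values.  Errors from a stage are
    re-raised as :class:`PipelineError` tagged with the stage name.
    """
    config = config or PipelineConfig()
    topology = sorted(
        {tuple(sorted((str(a), str(b)))) for a, b, *_ in (list(e) for e in topology)}
    )

    with _stage("phenotypes"):
        labels = set(expr.phenotype[list(expr.samples)])
        for lbl in (config.tumor_label, config.normal_label):
            if lbl not in labels:
                raise ValidationError(
                    f"phenotype {lbl!r} absent from expression matrix "
                    f"(available: {sorted(labels)})"
                )
        n_t = len(expr.phenotype_samples(config.tumor_label))
        n_n = len(expr.phenotype_samples(config.normal_label))

    with _stage("networks"):
        net_t = spearman_weights(
            expr, config.tumor_label, topology, strict=config.strict_spearman
        )
        net_n = spearman_weights(
            expr, config.normal_label, topology, strict=config.strict_spearman
        )

    with _stage("curvature"):
        curv_t = curvature_all_pairs(net_t, scope=config.scope)
        curv_n = curvature_all_pairs(net_n, scope=config.scope)

    with _stage("entropy"):
        ent_t = entropy_all_nodes(net_t)
        ent_n = entropy_all_nodes(net_n)

    with _stage("delta-curvature"):
        dk = delta_table(curv_t, curv_n)
        table_pairs = list(dk.data.index)
        rho_t = edge_spearman(
            expr, config.tumor_label, table_pairs, strict=config.strict_spearman
        )
        rho_n = edge_spearman(
            expr, config.normal_label, table_pairs, strict=config.strict_spearman
        )
        diff_co = pd.Series(
            {
                pair: differential_coexpression(rho_t[pair], rho_n[pair], n_t, n_n)
                for pair in table_pairs
            }
        )
        diff_co.index = pd.MultiIndex.from_tuples(diff_co.index)
        dk = dk.with_companion("diff_coexpression", diff_co)
        top, bottom = top_bottom(
            dk, min(config.top_k, len(dk))
        )

    with _stage("delta-nodal"):
        nodes = [
            x
            for x in net_t.nodes
            if net_t.node_strength(x) > 0 and net_n.node_strength(x) > 0
        ]
        nodal = pd.DataFrame({"node": nodes})
        for label, net in (("tumor", net_t), ("normal", net_n)):
            nodal[f"scalar_norm_{label}"] = [
                scalar_curvature_normalized(net, x) for x in nodes
            ]
            nodal[f"scalar_unnorm_{label}"] = [
                scalar_curvature_unnormalized(net, x) for x in nodes
            ]
        ent_t_idx = ent_t.set_index("node")
        ent_n_idx = ent_n.set_index("node")
        for kind in ("normalized", "unnormalized"):
            nodal[f"entropy_{kind[:6]}_tumor"] = ent_t_idx.loc[
                nodes, f"entropy_{kind}"
            ].to_numpy()
            nodal[f"entropy_{kind[:6]}_normal"] = ent_n_idx.loc[
                nodes, f"entropy_{kind}"
            ].to_numpy()
        for measure in ("scalar_norm", "scalar_unnorm", "entropy_normal", "entropy_unnorm"):
            tcol = f"{measure}_tumor" if measure != "entropy_normal" else "entropy_normal_tumor"
            ncol = f"{measure}_normal" if measure != "entropy_normal" else "entropy_normal_normal"
            nodal[f"delta_{measure}"] = nodal[tcol] - nodal[ncol]

    with _stage("gene-differential-expression"):
        adjacent_pairs = [p for p in table_pairs if net_t.has_edge(*p)]
        adj_diff = {p: diff_co[p] for p in adjacent_pairs}
        genes = sorted({g for e in topology for g in e})
        gde = pd.Series(
            {
                g: differential_expression_gene(adj_diff, topology, g)
                for g in genes
            }
        )

    with _stage("summary"):
        summary = {
            "n_tumor_samples": n_t,
            "n_normal_samples": n_n,
            "n_pairs": len(dk),
            "skipped_pairs": {
                "tumor": curv_t.skipped_pairs,
                "normal": curv_n.skipped_pairs,
            },
            "average_curvature": {
                "tumor": network_average_curvature(curv_t),
                "normal": network_average_curvature(curv_n),
            },
            "curvature": distribution_summary(
                delta_table(
                    CurvatureTable(curv_t.adjacent(), "adjacent"),
                    CurvatureTable(curv_n.adjacent(), "adjacent"),
                ),
                tail_fractions=config.tail_fractions,
            ),
            "wilcoxon_p": {},
        }
        adj_t = curv_t.adjacent().set_index(["node_a", "node_b"])["kappa"]
        adj_n = curv_n.adjacent().set_index(["node_a", "node_b"])["kappa"]
        adj_n = adj_n.reindex(adj_t.index)
        summary["wilcoxon_p"]["curvature_adjacent"] = wilcoxon_signed_rank_paired(
            adj_t.to_numpy(), adj_n.to_numpy()
        )
        for measure in ("scalar_norm", "scalar_unnorm", "entropy_normal", "entropy_unnorm"):
            col = f"delta_{measure}"
            vals = nodal[col].dropna()
            base = nodal.loc[vals.index]
            tcol = (
                f"{measure}_tumor"
                if measure != "entropy_normal"
                else "entropy_normal_tumor"
            )
            ncol = (
                f"{measure}_normal"
                if measure != "entropy_normal"
                else "entropy_normal_normal"
            )
            summary["wilcoxon_p"][measure] = wilcoxon_signed_rank_paired(
                base[tcol].to_numpy(), base[ncol].to_numpy()
            )
            summary.setdefault("delta_nodal_average", {})[measure] = float(
                vals.mean()
            )

    return DifferentialReport(
        config=config,
        curvature_tumor=curv_t,
        curvature_normal=curv_n,
        entropy_tumor=ent_t,
        entropy_normal=ent_n,
        delta_curvature=dk,
        delta_nodal=nodal,
        gene_differential_expression=gde,
        summary=summary,
        top=top,
        bottom=bottom,
    )
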