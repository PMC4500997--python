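"""Local network entropy of the one-step random walk.

The unnormalized local entropy at node ``x`` is the Shannon entropy of the
walk measure, ``-sum_y mu_x(y) log mu_x(y)`` (natural log by default); the
normalized variant divides by ``log deg(x)`` so that every node with equal
incident weights scores exactly 1 regardless of degree.  Degree-1 nodes
carry a point-mass walk measure; their normalized entropy is defined as 0
(the point-mass limit).

These are the nodal comparators against which scalar curvature is
benchmarked: across graph families, higher mean entropy goes with higher
mean curvature.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import IsolatedNodeError
from .graph_model import WeightedNetwork

__all__ = ["local_entropy", "entropy_all_nodes"]


def local_entropy(
    net: WeightedNetwork, x, normalized: bool = True, base: float | None = None
) -> float:
    """Shannon entropy of the walk measure at ``x``.

    Parameters
    ----------
    net, x
        Network and a non-isolated node.
    normalized
        Divide by ``log deg(x)`` (degree = neighbor count), mapping into
        [0, 1]; degree-1 nodes return 0 by convention.
    base
        Logarithm base; natural log when ``None``.  The base cancels in the
        normalized variant.
    """
    mu = net.node_measure(x)  # raises IsolatedNodeError for isolated nodes
    log = math.log if base is None else (lambda v: math.log(v, base))
    h = -math.fsum(m * log(m) for m in mu.mass if m > 0)
    if not normalized:
        return h
    deg = len(mu.support)
    if deg < 2:
        return 0.0
    return h / log(deg)


def entropy_all_nodes(net: WeightedNetwork) -> pd.DataFrame:
    """Both entropies for every node.

    Returns a DataFrame with columns ``node``, ``entropy_normalized``,
    ``entropy_unnormalized``; isolated nodes get NaN in both.
    """
    rows = []
    for x in net.nodes:
        try:
            rows.append(
                (x, local_entropy(net, x, True), local_entropy(net, x, False))
            )
        except IsolatedNodeError:
            rows.append((x, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["node", "entropy_normalized", "entropy_unnormalized"]
    )


def write_entropy_tsv(table: pd.DataFrame, path) -> None:
    """Serialize an entropy table as TSV (node, S_norm, S_unnorm)."""
    out = table.copy()
    for col in ("entropy_normalized", "entropy_unnormalized"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
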