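"""Graphlet-signature distances between two networks.

For a gene present in both networks, the per-orbit distance between its
two signature coordinates u and u' is

    D_i = w_i * |log(u_i + 1) - log(u'_i + 1)| / log(max(u_i, u'_i) + 2)

and the total *d-value* is sum_i D_i / sum_i w_i, a number in [0, 1):
0 exactly when the two signatures are identical, growing as the node's
local topology diverges between the two states.  Genes whose d-value
reaches the selection threshold (default 0.4, inclusive) form the
differential node set that seeds kernel-subgraph extraction.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .graphlets import N_ORBITS, count_orbits, orbit_dependency_weights

DEFAULT_D_THRESHOLD = 0.4


def orbit_distance(u_count: float, v_count: float, w_i: float) -> float:
    """Distance between one orbit coordinate of two signatures.

    Natural log is used; the value is base-invariant since the base
    cancels between numerator and denominator.
    """
    if u_count < 0 or v_count < 0:
        raise ValueError("orbit counts must be non-negative")
    num = abs(math.log(u_count + 1.0) - math.log(v_count + 1.0))
    den = math.log(max(u_count, v_count) + 2.0)
    return w_i * num / den


def d_value(sig_u, sig_v, weights: np.ndarray | None = None) -> float:
    """Total signature distance between two 15-vectors, in [0, 1)."""
    sig_u = np.asarray(sig_u, dtype=float)
    sig_v = np.asarray(sig_v, dtype=float)
    if sig_u.shape != (N_ORBITS,) or sig_v.shape != (N_ORBITS,):
        raise ValueError(f"signatures must have length {N_ORBITS}")
    w = orbit_dependency_weights(weights) if weights is not None else orbit_dependency_weights()
    total = sum(
        orbit_distance(sig_u[i], sig_v[i], w[i]) for i in range(N_ORBITS)
    )
    return total / w.sum()


def differential_nodes(
    net_a: nx.Graph,
    net_b: nx.Graph,
    weights: np.ndarray | None = None,
    threshold: float = DEFAULT_D_THRESHOLD,
) -> pd.DataFrame:
    """d-value of every common gene and its selection flag.

    Parameters
    ----------
    net_a, net_b : networkx.Graph
        The two state networks; must share at least one node.
    weights : array-like of length 15, optional
        Orbit weight override (default: dependency-derived weights).
    threshold : float
        Selection cut; genes with ``d_value >= threshold`` enter the
        differential node set.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene, columns ``d_value`` (float) and ``selected``
        (bool), sorted by d-value descending then gene name.
    """
    common = sorted(set(net_a.nodes) & set(net_b.nodes))
    if not common:
        raise ValueError("networks share no common nodes")
    sig_a = count_orbits(net_a)
    sig_b = count_orbits(net_b)
    d = [
        d_value(sig_a.loc[g].to_numpy(), sig_b.loc[g].to_numpy(), weights)
        for g in common
    ]
    table = pd.DataFrame({"d_value": d}, index=pd.Index(common, name="gene"))
    table["selected"] = table["d_value"] >= threshold
    table = table.sort_values(
        by=["d_value", "gene"], ascending=[False, True], kind="mergesort"
    )
    table.attrs["threshold"] = threshold
    return table
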