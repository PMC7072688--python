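"""Synthetic benchmark generator with a planted essential-gene module.

Each simulated pair emulates a two-state perturbation experiment:

1. a scale-free base network G on ``n1`` genes (preferential
   attachment with triangle closure, so neighbourhoods are clustered
   as in real interactomes) is the state-A network;
2. the ``m`` *essential genes* are a randomly grown connected module
   seeded at a preferentially high-degree gene — the classic
   planted-module design: a perturbation hits a coherent functional
   neighbourhood, not m isolated genes;
3. the state-B network G' is G with exactly ``ceil(rho * |E(G)|)``
   edge differences, every one incident to an essential gene.
   Differences are realised pairwise as a removal plus an addition.
   Each module gene is independently marked *disrupted* (probability
   ``disruption_rate``); removals strip the disrupted genes down to a
   couple of remaining edges — their best-connected partner is never
   removed, so every gene stays attached to the network's core in
   both states — while the passenger genes only gain unestablished
   partners.  Real perturbations have focal genes and passengers,
   and it is the focal, heavily rewired genes whose graphlet
   signatures shift measurably.  A tunable fraction of removals
   takes intra-module edges (one removal then disturbs two module
   genes, and the module re-connects through shared hubs).  ``rho``
   is the proportion of differential edges; the smaller it is, the
   harder the planted genes are to find;
4. per state, expression for ``samples_per_state`` cells is drawn
   from a zero-mean Gaussian whose precision matrix is that state's
   weighted graph Laplacian plus ``laplacian_shift`` times the
   identity; log-normal edge couplings (``exp(N(0, coupling_sigma))``)
   are keyed deterministically to the gene pair so shared edges
   behave identically in both states.  The uniform zero-eigenvalue
   mode is dropped so correlation follows edges rather than a global
   trend; profiles are standardised per gene, degraded with i.i.d.
   observation noise of sd ``noise_sd`` and mapped to CPM-like values
   via 2**(mu + sd_log * z) - 1;
5. each state network carries |PCC| edge weights computed from its
   own expression, exactly as the preprocessing stage would assign
   them.

Everything is driven by a single integer seed; identical configs give
byte-identical pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Study conditions for one simulated pair (defaults are calibrated
    once and frozen; see docs/methods.md)."""

    n1: int = 100
    n2: int = 100
    m: int = 10
    rho: float = 0.1
    samples_per_state: int = 100
    attachment: int = 6
    triangle_p: float = 0.5
    n_peripheral: int = 20
    module_satellites: int = 0
    disruption_rate: float = 0.7
    hub_cap: int = 7
    partner_focus: float = 2.0
    intra_removal_bias: float = 0.45
    linker_p: float = 0.0
    noise_sd: float = 0.3
    coupling_sigma: float = 1.5
    weight_boost: float = 1.0
    laplacian_shift: float = 0.1
    log_mean: float = 7.0
    log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.m >= min(self.n1, self.n2):
            raise ValueError("m must be smaller than min(n1, n2)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.n1 != self.n2:
            raise ValueError("the two states share one gene universe; n1 must equal n2")


@dataclass
class SimulatedPair:
    """Two state networks + planted truth + expression, fully seeded."""

    net_a: nx.Graph
    net_b: nx.Graph
    essential: list
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def _gene_name(i: int) -> str:
    return f"g{i:03d}"


def _edge_coupling(pair_seed: int, u: str, v: str, sigma: float) -> float:
    """Log-normal co-expression coupling, deterministic per (pair, gene
    pair) so that an edge present in both state networks couples
    identically in both."""
    i, j = sorted((int(u[1:]), int(v[1:])))
    rng = np.random.default_rng([pair_seed, i, j])
    return float(np.exp(rng.normal(0.0, sigma)))


def _planted_module(base: nx.Graph, m: int, min_deg: int, hub_cap: int, linker_p: float, rng) -> list:
    """Grow a near-connected set of m mid/high-degree genes.

    The walk is seeded preferentially at a well-connected gene and
    expands through the frontier, avoiding extreme hubs (degree above
    ``hub_cap``) while any alternative exists: a perturbation of a
    top hub barely dents its neighbourhood fractionally, so realistic
    disease modules sit in the mid-degree range.  With probability
    ``linker_p`` a growth step jumps two hops, leaving an unperturbed
    non-essential *linker* gene inside the module's span — pathways
    routinely pass through genes the perturbation does not touch.
    """
    genes = sorted(base.nodes)
    degrees = np.array(
        [min(base.degree(g), hub_cap) if base.degree(g) >= min_deg else 0.0
         for g in genes]
    )
    weight = dict(zip(genes, np.maximum(degrees, 1e-9)))
    seed_gene = str(rng.choice(genes, p=degrees / degrees.sum()))
    module = {seed_gene}
    while len(module) < m:
        frontier = sorted({t for g in module for t in base[g]} - module)
        if not frontier:  # cannot happen on a connected base graph
            raise ValueError("base graph too small for a connected module")
        if rng.random() < linker_p:
            linker = frontier[rng.integers(len(frontier))]
            two_hop = sorted(set(base[linker]) - module - set(frontier))
            if two_hop:
                module.add(two_hop[rng.integers(len(two_hop))])
                continue
        mid = [t for t in frontier if min_deg <= base.degree(t) <= hub_cap]
        if not mid:  # no mid-degree frontier: take the least-hubby genes
            lo = min(base.degree(t) for t in frontier)
            mid = [t for t in frontier if base.degree(t) <= lo + 1]
        pool = mid
        p = np.array([weight[t] for t in pool])
        module.add(pool[rng.choice(len(pool), p=p / p.sum())])
    return sorted(module)


def _perturb(
    base: nx.Graph, essential, n_diff: int, disruption_rate: float, focus: float, intra_bias: float, rng
) -> nx.Graph:
    """Return a copy of ``base`` differing in exactly ``n_diff`` edges,
    each incident to an essential gene.

    Differences are realised pairwise as a removal plus an addition
    (plus one pure deletion when ``n_diff`` is odd), so |E| is
    approximately preserved.  Each module gene is independently marked
    *disrupted* with probability ``disruption_rate``; removals strip
    the disrupted genes one at a time down to ~2 remaining edges
    (never the best-connected partner, which anchors the gene to the
    network's core in both states), so they lose most of their
    neighbourhood while the passenger genes — which only gain
    unestablished partners — are barely touched.  Real perturbations
    have focal genes and passengers.  With probability ``intra_bias``
    a removal prefers an intra-module edge (disturbing two module
    genes at once); otherwise edges leaving the module go first.
    """
    net = base.copy()
    removed: set = set()
    added: set = set()
    ess_set = set(essential)
    hit_partners: set = set()
    order = list(essential)
    rng.shuffle(order)
    flags = rng.random(len(order)) < disruption_rate
    if not flags.any():
        flags[0] = True
    disrupted = [g for g, f in zip(order, flags) if f]
    passengers = [g for g, f in zip(order, flags) if not f] or disrupted

    def free_edges(g, floor=2, prefer_intra=False):
        # a disrupted gene keeps ~2 edges: deep enough for a clear
        # signature change, while staying attached in both states
        if net.degree(g) <= floor:
            return []
        out, intra = [], []
        for t in net[g]:
            e = frozenset((g, t))
            if e in added or e in removed:
                continue
            (intra if t in ess_set else out).append(t)
        # an intra-module removal disturbs two module genes at once and
        # re-connects the module through shared hub anchors; an
        # out-of-module removal damages one gene but spares the module
        if prefer_intra:
            return sorted(intra) or sorted(out)
        return sorted(out) or sorted(intra)

    diff = 0
    while diff < n_diff:
        cand = [g for g in disrupted if free_edges(g)]
        if not cand:  # budget left over: strip disrupted genes deeper
            cand = [g for g in disrupted if free_edges(g, floor=1)]
        if not cand:
            cand = [g for g in order if free_edges(g, floor=1)]
        if not cand:
            # no removable edge left anywhere: realise the remaining
            # differences as additions alone
            if not _gain(rng, passengers, net, base, removed, added, hit_partners,
                         ess_set, focus):
                raise ValueError("rewiring infeasible; try a lower rho")
            diff += 1
            continue
        anchor = cand[0]  # strip genes to completion, one at a time
        anchor_edges = free_edges(anchor, floor=1, prefer_intra=rng.random() < intra_bias)
        # the best-connected partner is never removed: the stripped
        # gene stays anchored to the network's core in both states
        protect = max(net[anchor], key=lambda t: (net.degree(t), t))
        targets = [t for t in anchor_edges if net.degree(t) >= 2 and t != protect]
        if not targets:
            targets = [t for t in anchor_edges if t != protect] or anchor_edges
        # well-connected partners absorb the loss; low-degree satellite
        # partners keep their edge and feel the disruption passively
        tw = np.array([float(net.degree(t)) ** 2 for t in targets])
        t_rm = targets[rng.choice(len(targets), p=tw / tw.sum())]
        net.remove_edge(anchor, t_rm)
        removed.add(frozenset((anchor, t_rm)))
        if t_rm not in ess_set:
            hit_partners.add(t_rm)
        diff += 1
        if diff >= n_diff:
            break
        # addition: a passenger essential gene gains a fresh partner
        if _gain(rng, passengers, net, base, removed, added, hit_partners,
                 ess_set, focus):
            diff += 1
    return net


def _gain(rng, passengers, net, base, removed, added, hit_partners, ess_set, focus):
    """Add one fresh essential-incident edge; returns False if no
    legal addition exists anywhere."""
    gain_cand = []
    for g in passengers:
        partners = [
            t for t in net.nodes
            if t != g
            and not net.has_edge(g, t)
            and not base.has_edge(g, t)
            and frozenset((g, t)) not in removed
        ]
        if partners:
            gain_cand.append((g, sorted(partners)))
    if not gain_cand:
        return False
    g, partners = gain_cand[rng.integers(len(gain_cand))]
    # recruitment into a complex: prefer partners that close a
    # triangle with the gaining gene's current neighbourhood, so
    # gained structure is clustered rather than a loose star
    nbrs = set(net[g])
    closing = [t for t in partners if nbrs & set(net[t])]
    pool = closing or partners
    pw = np.array([
        1.0 + 10.0 * focus * (t in hit_partners) for t in pool
    ])
    t = pool[rng.choice(len(pool), p=pw / pw.sum())]
    net.add_edge(g, t)
    added.add(frozenset((g, t)))
    if t not in ess_set:
        hit_partners.add(t)
    return True


def _expression(net: nx.Graph, genes, config: SimulationConfig, boosted, core_deg, rng) -> ExpressionMatrix:
    """Weighted-Laplacian Gaussian expression for one state.

    Edges incident to a ``boosted`` (essential) gene couple more
    strongly: an active disease module co-expresses above background,
    which is what makes edge weight a biologically meaningful growth
    criterion alongside the signature distance.
    """
    n, n_cells = len(genes), config.samples_per_state
    idx = {g: i for i, g in enumerate(genes)}
    lap = np.zeros((n, n))
    for u, v in net.edges:
        w = _edge_coupling(config.seed, u, v, config.coupling_sigma)
        if (u in boosted or v in boosted) and min(core_deg[u], core_deg[v]) > 0:
            w *= config.weight_boost
        i, j = idx[u], idx[v]
        lap[i, j] -= w
        lap[j, i] -= w
        lap[i, i] += w
        lap[j, j] += w
    vals, vecs = np.linalg.eigh(lap)
    keep = vals > 1e-9  # drop each component's uniform zero mode
    scale = 1.0 / np.sqrt(vals[keep] + config.laplacian_shift)
    coeff = rng.standard_normal((int(keep.sum()), n_cells)) * scale[:, None]
    z = vecs[:, keep] @ coeff
    sd = z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    z = z + rng.normal(0.0, config.noise_sd, size=z.shape)
    z = z / math.sqrt(1.0 + config.noise_sd**2)
    log_expr = config.log_mean + config.log_sd * z
    values = np.maximum(2.0**log_expr - 1.0, 0.0)
    df = pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene"),
        columns=[f"cell{j:03d}" for j in range(n_cells)],
    )
    return ExpressionMatrix(df, "cpm")


def _attach_pcc_weights(net: nx.Graph, expr: ExpressionMatrix) -> None:
    log_expr = np.log2(expr.data.to_numpy() + 1.0)
    row = {g: i for i, g in enumerate(expr.genes)}
    for u, v in net.edges:
        x, y = log_expr[row[u]], log_expr[row[v]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            net[u][v]["weight"] = 0.0
            continue
        net[u][v]["weight"] = min(abs(float(np.corrcoef(x, y)[0, 1])), 1.0)


def generate_pair(config: SimulationConfig) -> SimulatedPair:
    """Generate one simulated two-state pair from its config (seeded)."""
    rng = np.random.default_rng(config.seed)
    graph_seed = int(rng.integers(2**31 - 1))
    n_core = config.n1 - config.n_peripheral
    base = nx.powerlaw_cluster_graph(
        n_core, config.attachment, config.triangle_p, seed=graph_seed
    )
    genes = [_gene_name(i) for i in range(config.n1)]
    base = nx.relabel_nodes(base, dict(zip(range(n_core), genes)))

    essential = _planted_module(base, config.m, config.attachment, config.hub_cap, config.linker_p, rng)

    # low-degree periphery: satellite genes with 1-2 attachments give
    # the network the degree-1-2 fringe real interactomes have.  The
    # first few are the module's own periphery (substrates/adaptors
    # bound to essential genes); the rest attach preferentially across
    # the whole network.
    for i in range(n_core, config.n1):
        if i - n_core < config.module_satellites:
            hosts = essential
            deg = np.ones(len(hosts))
            k = 2  # a module satellite bridges two essential genes
        else:
            hosts = sorted(base.nodes)
            deg = np.array([base.degree(h) for h in hosts], dtype=float)
            k = 1 + int(rng.integers(2))
        picked = rng.choice(hosts, size=min(k, len(hosts)), replace=False, p=deg / deg.sum())
        base.add_node(genes[i])
        for h in picked:
            base.add_edge(genes[i], str(h))

    n_diff = math.ceil(config.rho * base.number_of_edges())
    net_b = _perturb(base, essential, n_diff, config.disruption_rate, config.partner_focus, config.intra_removal_bias, rng)
    net_a = base

    boosted = set(essential)
    # peripheral satellites are not part of the module's established
    # co-expression: only edges between core genes are boosted
    core_deg = {g: (base.degree(g) if int(g[1:]) < n_core else 0) for g in genes}
    expr_a = _expression(net_a, genes, config, boosted, core_deg, rng)
    expr_b = _expression(net_b, genes, config, boosted, core_deg, rng)
    _attach_pcc_weights(net_a, expr_a)
    _attach_pcc_weights(net_b, expr_b)
    return SimulatedPair(net_a, net_b, list(essential), expr_a, expr_b, config.seed, config)


def generate_dataset(
    config: SimulationConfig, n_pairs: int, master_seed: int
) -> list[SimulatedPair]:
    """``n_pairs`` independent pairs with per-pair seeds derived from
    ``master_seed`` (deterministic; distinct seeds guaranteed)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(master_seed)
    seeds = []
    seen = set()
    while len(seeds) < n_pairs:
        s = int(rng.integers(2**31 - 1))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return [generate_pair(replace(config, seed=s)) for s in seeds]
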