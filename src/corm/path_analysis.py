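"""Flux-graph construction, production-path enumeration, and pathway entropy.

The integrated net flux of every reaction over the simulation window defines a
directed graph on enzyme states: each reversible binding pair contributes at
most one edge (oriented by the sign of the integrated net flux), and each
turnover reaction contributes an edge from its complex to the regenerated
state, annotated with the released product.

A *production path* for a product is a simple edge sequence from the free
enzyme to a turnover edge releasing that product.  Turnover edges may also be
traversed internally, releasing a co-product en route (this is what makes a
sixth PG path and a fourth PG-G path possible).  Path fluxes are apportioned
backward from each terminal edge: at every upstream node the mass is split
over the allowed incoming edges (those not revisiting a downstream node of
the path) in proportion to their integrated flux.  Excluding revisiting edges
and renormalizing makes the decomposition conserve the total product formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corm_model import FREE_ENZYME_ID, ReactionNetwork
from .kinetics import InitialCondition, ParameterSet, Trajectory, simulate

__all__ = [
    "FluxEdge",
    "FluxGraph",
    "ProductionPath",
    "PathFluxDistribution",
    "build_flux_graph",
    "enumerate_paths",
    "apportion_path_flux",
    "pathway_entropy",
    "entropy_grid",
    "path_report",
    "DEFAULT_AA_GRID",
    "DEFAULT_AG_GRID",
]

#: Substrate-concentration grids used for the path-flux and entropy landscapes.
DEFAULT_AA_GRID: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_AG_GRID: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

_PRODUCT_ALIASES = {"PG": "PG", "PGG": "PGG", "PG-G": "PGG"}


def _canonical_product(product: str, graph: "FluxGraph | None" = None) -> str:
    if product in _PRODUCT_ALIASES:
        return _PRODUCT_ALIASES[product]
    if graph is not None and any(e.product == product for e in graph.terminal_edges):
        return product  # non-canonical product names occur in toy fixtures
    raise ValueError(f"unknown product {product!r}; expected 'PG' or 'PG-G'")


@dataclass(frozen=True)
class FluxEdge:
    """A directed edge carrying integrated net flux (uM) over the window."""

    source: str
    target: str
    flux: float
    kind: str  # "net_binding" | "turnover"
    reaction_ids: tuple[str, ...]
    product: str | None = None  # set for turnover edges

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class FluxGraph:
    """Directed graph of integrated net fluxes between enzyme states."""

    nodes: tuple[str, ...]
    edges: tuple[FluxEdge, ...]
    source: str = FREE_ENZYME_ID

    def out_edges(self, node: str) -> tuple[FluxEdge, ...]:
        return tuple(e for e in self.edges if e.source == node)

    def in_edges(self, node: str) -> tuple[FluxEdge, ...]:
        return tuple(e for e in self.edges if e.target == node)

    @property
    def terminal_edges(self) -> tuple[FluxEdge, ...]:
        return tuple(e for e in self.edges if e.kind == "turnover")

    def total_product_flux(self, product: str) -> float:
        product = _canonical_product(product, self)
        return sum(e.flux for e in self.terminal_edges if e.product == product)


@dataclass(frozen=True)
class ProductionPath:
    """Ordered edges from the free enzyme to a terminal turnover edge."""

    product: str
    edges: tuple[FluxEdge, ...]
    flux: float | None = None
    share: float | None = None

    @property
    def co_products(self) -> tuple[str, ...]:
        return tuple(
            e.product for e in self.edges[:-1] if e.kind == "turnover" and e.product is not None
        )

    @property
    def node_sequence(self) -> tuple[str, ...]:
        return (self.edges[0].source,) + tuple(e.target for e in self.edges)

    @property
    def label(self) -> str:
        return " | ".join(
            f"{e.source} ={e.product}=> {e.target}" if e.kind == "turnover" else e.label
            for e in self.edges
        )


@dataclass(frozen=True)
class PathFluxDistribution:
    """Per-product path set with apportioned fluxes and normalized shares."""

    product: str
    paths: tuple[ProductionPath, ...]
    total_product: float
    empty: bool = False

    @property
    def probabilities(self) -> np.ndarray:
        fluxes = np.array([p.flux for p in self.paths], dtype=float)
        total = fluxes.sum()
        if self.empty or total <= 0:
            return np.full(len(self.paths), np.nan)
        return fluxes / total


def build_flux_graph(
    traj: Trajectory,
    network: ReactionNetwork,
    zero_tol: float = 1e-12,
) -> FluxGraph:
    """Integrate net reaction fluxes by trapezoidal quadrature and orient edges.

    Each (binding, unbinding) pair collapses to one directed edge carrying
    |integrated forward - integrated reverse|; pairs with |net| < ``zero_tol``
    uM contribute no edge.  Every turnover reaction with integrated flux above
    ``zero_tol`` contributes a product-annotated edge to the state it
    regenerates.
    """
    integrated = {
        rid: float(np.trapezoid(traj.rate_of(rid), traj.times)) for rid in traj.reaction_ids
    }
    nodes = network.enzyme_state_ids
    enzyme_nodes = set(nodes)

    def enzyme_endpoint(pairs: Iterable[tuple[str, int]]) -> str:
        for sid, _ in pairs:
            if sid in enzyme_nodes:
                return sid
        raise ValueError("reaction without an enzyme-state endpoint")

    edges: list[FluxEdge] = []
    for rx in network.reactions:
        if rx.kind == "binding":
            rev_id = network.reverse_of(rx.id)
            net = integrated[rx.id] - integrated[rev_id]
            if abs(net) < zero_tol:
                continue
            free_state = enzyme_endpoint(rx.reactants)
            bound_state = enzyme_endpoint(rx.products)
            if net > 0:
                edges.append(FluxEdge(free_state, bound_state, net, "net_binding", (rx.id, rev_id)))
            else:
                edges.append(FluxEdge(bound_state, free_state, -net, "net_binding", (rev_id, rx.id)))
        elif rx.kind == "turnover":
            flux = integrated[rx.id]
            if flux < zero_tol:
                continue
            complex_state = enzyme_endpoint(rx.reactants)
            regenerated = enzyme_endpoint(rx.products)
            product = next(sid for sid, _ in rx.products if sid not in enzyme_nodes)
            edges.append(FluxEdge(complex_state, regenerated, flux, "turnover", (rx.id,), product))
    return FluxGraph(tuple(nodes), tuple(edges))


def enumerate_paths(graph: FluxGraph, product: str) -> list[ProductionPath]:
    """All simple production paths for ``product`` (fluxes not yet assigned).

    Depth-first traversal from the free enzyme node.  A path terminates on a
    turnover edge releasing ``product``; turnover edges releasing other
    products may be traversed internally (their regenerated state becomes the
    next node).  No enzyme-state node is visited twice; the final edge's
    regenerated state is exempt because the path ends before reaching it.
    """
    product = _canonical_product(product, graph)
    out: dict[str, list[FluxEdge]] = {n: [] for n in graph.nodes}
    for e in graph.edges:
        out[e.source].append(e)
    for n in out:
        out[n].sort(key=lambda e: (e.kind, e.target))

    paths: list[ProductionPath] = []

    def dfs(node: str, visited: set[str], trail: list[FluxEdge]) -> None:
        for e in out[node]:
            if e.kind == "turnover" and e.product == product:
                paths.append(ProductionPath(product, tuple(trail + [e])))
            if e.target in visited:
                continue
            visited.add(e.target)
            trail.append(e)
            dfs(e.target, visited, trail)
            trail.pop()
            visited.remove(e.target)

    dfs(graph.source, {graph.source}, [])
    return paths


def apportion_path_flux(
    graph: FluxGraph,
    paths: Sequence[ProductionPath],
) -> PathFluxDistribution:
    """Apportion each terminal edge's flux over the paths that reach it.

    Walking backward along a path from the terminal complex, the mass at each
    node splits over its incoming edges in proportion to integrated flux,
    excluding edges that would revisit a node already on the downstream
    portion of the path (the split is renormalized over the remaining edges).
    The resulting path fluxes sum to the product's total formation, up to
    quadrature error and backward dead ends.
    """
    if not paths:
        return PathFluxDistribution("", (), 0.0, empty=True)
    product = paths[0].product
    total_product = graph.total_product_flux(product)
    if total_product <= 0:
        return PathFluxDistribution(product, tuple(paths), 0.0, empty=True)

    influx: dict[str, list[FluxEdge]] = {n: [] for n in graph.nodes}
    for e in graph.edges:
        influx[e.target].append(e)

    resolved: list[ProductionPath] = []
    for path in paths:
        nodes = path.node_sequence
        weight = path.edges[-1].flux
        # Backward over internal nodes nodes[1..m-1]; nodes[m] is the final
        # regenerated state (never entered) and nodes[0] the source.
        for k in range(len(path.edges) - 1, 0, -1):
            node = nodes[k]
            downstream = set(nodes[k:-1])
            allowed = [e for e in influx[node] if e.source not in downstream]
            z = sum(e.flux for e in allowed)
            if z <= 0:
                weight = 0.0
                break
            weight *= path.edges[k - 1].flux / z
        resolved.append(replace(path, flux=weight, share=weight / total_product))
    return PathFluxDistribution(product, tuple(resolved), total_product)


def pathway_entropy(dist: PathFluxDistribution) -> float:
    """Shannon entropy (bits) of the normalized path-flux shares.

    ``0 * log 0`` is taken as 0.  Returns NaN (not 0) for an empty
    distribution: entropy is undefined when no product is formed.
    """
    if dist.empty or len(dist.paths) == 0:
        return math.nan
    p = dist.probabilities
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _analyse_condition(
    network: ReactionNetwork,
    params: ParameterSet,
    init: InitialCondition,
    T: float,
    n_points: int,
    **sim_kwargs,
) -> dict[str, PathFluxDistribution]:
    traj = simulate(network, params, init, T=T, n_points=n_points, **sim_kwargs)
    graph = build_flux_graph(traj, network)
    out = {}
    for product in ("PG", "PGG"):
        paths = enumerate_paths(graph, product)
        out[product] = apportion_path_flux(graph, paths) if paths else PathFluxDistribution(
            product, (), graph.total_product_flux(product), empty=True
        )
    return out


def entropy_grid(
    network: ReactionNetwork,
    params: ParameterSet,
    AA_values: Sequence[float] = DEFAULT_AA_GRID,
    AG_values: Sequence[float] = DEFAULT_AG_GRID,
    *,
    E0: float = 0.015,
    T: float = 10.0,
    n_points: int = 501,
    **sim_kwargs,
) -> pd.DataFrame:
    """Pathway entropy for both products over a substrate-concentration grid.

    One simulation and path analysis per (AA0, AG0) cell.  Cells where a
    product is not formed are flagged ``no_product`` with NaN entropy rather
    than silently reported as zero entropy.
    """
    if len(AA_values) == 0 or len(AG_values) == 0:
        raise ValueError("concentration grids must be non-empty")
    rows = []
    for aa in AA_values:
        for ag in AG_values:
            dists = _analyse_condition(
                network, params, InitialCondition(E0, aa, ag), T, n_points, **sim_kwargs
            )
            for product, dist in dists.items():
                rows.append(
                    {
                        "AA0": aa,
                        "AG0": ag,
                        "product": product,
                        "entropy_bits": pathway_entropy(dist),
                        "n_active_paths": int(sum(1 for p in dist.paths if (p.flux or 0) > 0)),
                        "total_product": dist.total_product,
                        "flag": "no_product" if dist.empty else "",
                    }
                )
    return pd.DataFrame(rows)


def path_report(
    network: ReactionNetwork,
    params: ParameterSet,
    AA_values: Sequence[float] = DEFAULT_AA_GRID,
    AG_values: Sequence[float] = DEFAULT_AG_GRID,
    *,
    E0: float = 0.015,
    T: float = 10.0,
    n_points: int = 501,
    **sim_kwargs,
) -> pd.DataFrame:
    """Long-form per-condition path fluxes over a substrate grid."""
    rows = []
    for aa in AA_values:
        for ag in AG_values:
            dists = _analyse_condition(
                network, params, InitialCondition(E0, aa, ag), T, n_points, **sim_kwargs
            )
            for product, dist in dists.items():
                if dist.empty:
                    continue
                for i, path in enumerate(dist.paths):
                    rows.append(
                        {
                            "AA0": aa,
                            "AG0": ag,
                            "product": product,
                            "path_id": f"{product}_path_{i}",
                            "path": path.label,
                            "co_products": ";".join(path.co_products),
                            "flux_uM": path.flux,
                            "share": path.share,
                        }
                    )
    return pd.DataFrame(rows)
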