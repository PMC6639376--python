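"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or direct
summation, sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def enumerate_walks_brute_force(graph, product):
    """All source-to-terminal walks without node revisits, by plain recursion.

    Returns a list of edge tuples, each ending on a turnover edge releasing
    ``product``.  Internal turnover edges may be traversed.
    """
    out = {}
    for e in graph.edges:
        out.setdefault(e.source, []).append(e)
    walks = []

    def step(node, seen, acc):
        for e in out.get(node, []):
            if e.kind == "turnover" and e.product == product:
                walks.append(tuple(acc + [e]))
            if e.target not in seen:
                step(e.target, seen | {e.target}, acc + [e])

    step(graph.source, {graph.source}, [])
    return walks


def apportion_brute_force(graph, walks):
    """Walk fluxes by direct multiplication of incoming-flux fractions.

    For each walk, the terminal edge's flux is multiplied at every upstream
    node by the fraction of that node's total incoming flux carried by the
    walk's incoming edge.  (On DAGs this matches the package's conditioned
    scheme, since no incoming edge can originate downstream.)
    """
    influx = {}
    for e in graph.edges:
        influx.setdefault(e.target, []).append(e)
    fluxes = []
    for walk in walks:
        mass = walk[-1].flux
        nodes = [walk[0].source] + [e.target for e in walk]
        for k in range(len(walk) - 1, 0, -1):
            total = sum(e.flux for e in influx[nodes[k]])
            mass *= walk[k - 1].flux / total
        fluxes.append(mass)
    return fluxes


def mutual_information_brute_force(counts):
    """Term-by-term plug-in mutual information (bits) from a count table."""
    n = sum(sum(row) for row in counts)
    nx = len(counts)
    ny = len(counts[0])
    row_tot = [sum(counts[i]) for i in range(nx)]
    col_tot = [sum(counts[i][j] for i in range(nx)) for j in range(ny)]
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            if counts[i][j] == 0:
                continue
            pxy = counts[i][j] / n
            px = row_tot[i] / n
            py = col_tot[j] / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def shannon_entropy_brute_force(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


def bsc_capacity_closed_form(p):
    """1 - H2(p), the binary symmetric channel capacity."""
    h2 = -p * math.log2(p) - (1 - p) * math.log2(1 - p)
    return 1.0 - h2
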