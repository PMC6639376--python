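"""Synthetic inputs for the analysis: parameter ensembles and substrate samples.

The calibrated posterior over rate constants is not publicly available, so
ensembles here are log-uniform clouds around a nominal, thermodynamically
consistent parameter set.  Cycle closure is enforced exactly by deriving one
unbinding rate per two-ligand binding cycle from the other three equilibrium
constants; qualitative allosteric constraints (see ``KCAT_ORDERINGS``) are
enforced by resampling.  The nominal values are uncalibrated stand-ins chosen
so that (a) each substrate alone is turned over with similar catalytic
efficiency, (b) allosteric-site association is an order of magnitude slower
than catalytic-site association, so allosteric-first binding paths are
kinetically disfavored, and (c) allosteric occupancy raises AA turnover and
lowers 2-AG turnover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corm_model import binding_cycles, build_corm
from .kinetics import ParameterSet
from .path_analysis import FluxEdge, FluxGraph

__all__ = [
    "EnsembleSpec",
    "InputSample",
    "GenerationError",
    "nominal_parameters",
    "generate_parameter_ensemble",
    "sample_inputs",
    "make_toy_flux_graph",
    "ensemble_to_json",
    "ensemble_from_json",
    "KCAT_ORDERINGS",
    "TOY_GRAPH_NAMES",
]


class GenerationError(RuntimeError):
    """Constraint-satisfying samples could not be generated."""


#: Qualitative turnover-rate orderings: (faster, slower) kcat names.
#: Allosteric occupancy enhances AA turnover and suppresses 2-AG turnover.
KCAT_ORDERINGS: tuple[tuple[str, str], ...] = (
    ("kcat_AA__allo_AA", "kcat_AA__allo_EMPTY"),
    ("kcat_AA__allo_AG", "kcat_AA__allo_EMPTY"),
    ("kcat_AG__allo_EMPTY", "kcat_AG__allo_AA"),
)

# One unbinding rate per binding cycle is derived, never sampled, so that the
# cycle's K-product is exactly 1.
_DERIVED_KR = (
    "kr_cat_AA__allo_AA",
    "kr_cat_AA__allo_AG",
    "kr_cat_AG__allo_AA",
    "kr_cat_AG__allo_AG",
)

# Nominal dissociation constants (uM) depend only on the site, which closes
# every binding cycle automatically AND keeps every binding pair net-forward
# over the catalysis window at any substrate mix: if per-site on-rate ratios
# differed from equilibrium ratios, early kinetic overshoot would drain back
# later and flip integrated net fluxes, changing the path topology mid-grid.
# Catalytic association is fast (10 per uM s); allosteric tenfold slower.
_NOMINAL_KD = {
    ("cat", "AA"): 1.0,
    ("cat", "AG"): 1.0,
    ("allo", "AA"): 2.0,
    ("allo", "AG"): 2.0,
}
_NOMINAL_KF = {"cat": 10.0, "allo": 1.0}

# Turnover rates (1/s).  Deliberately slow relative to binding so that flux
# over the 10 s window is dominated by first-passage binding rather than
# repeated enzyme recycling, which keeps the path decomposition conservative.
_NOMINAL_KCAT = {
    "kcat_AA__allo_EMPTY": 2.0e-3,
    "kcat_AA__allo_AA": 6.0e-3,
    "kcat_AA__allo_AG": 8.0e-3,
    "kcat_AG__allo_EMPTY": 1.8e-3,
    "kcat_AG__allo_AA": 0.9e-3,
}


def nominal_parameters(name: str = "nominal") -> ParameterSet:
    """The nominal (uncalibrated, clearly stand-in) parameter set."""
    values: dict[str, float] = {}
    network = build_corm()
    for rx in network.reactions:
        ref = rx.rate_constant_ref
        if rx.kind == "binding":
            site = "cat" if rx.site == "catalytic" else "allo"
            values[ref] = _NOMINAL_KF[site]
        elif rx.kind == "unbinding":
            site = "cat" if rx.site == "catalytic" else "allo"
            ligand = ref.split("__")[0].rsplit("_", 1)[-1]
            values[ref] = _NOMINAL_KF[site] * _NOMINAL_KD[(site, ligand)]
    values.update(_NOMINAL_KCAT)
    return ParameterSet(values, name=name)


@dataclass(frozen=True)
class EnsembleSpec:
    """How to draw a stand-in parameter ensemble around the nominal values."""

    n_sets: int = 20
    log10_range: float = 1.0  # total sampled decades per parameter, <= 3
    seed: int = 0
    max_resamples: int = 10_000

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if not 0 <= self.log10_range <= 3:
            raise ValueError("log10_range must lie in [0, 3]")


def _cycle_kr_derivation() -> list[tuple[str, tuple]]:
    """Map each derived kr name to the cycle legs that determine it."""
    out = []
    for cyc in binding_cycles():
        (kf1, kr1), (kf2, kr2) = cyc["numerator"]
        (kf3, kr3), (kf4, kr4) = cyc["denominator"]
        # K4 = K1 * K2 / K3  =>  kr4 = kf4 * K3 / (K1 * K2)
        out.append((kr4, (kf4, kf1, kr1, kf2, kr2, kf3, kr3)))
    return out


def generate_parameter_ensemble(spec: EnsembleSpec) -> list[ParameterSet]:
    """Draw ``spec.n_sets`` thermodynamically consistent parameter sets.

    Each free kf/kr/kcat is log-uniform within ``log10_range`` decades centred
    on its nominal value.  The four cycle-derived unbinding rates are computed
    from the other equilibrium constants, so cycle closure holds exactly.
    kcat draws violating :data:`KCAT_ORDERINGS` are resampled (up to
    ``max_resamples`` times).
    """
    rng = np.random.default_rng(spec.seed)
    nominal = nominal_parameters().as_dict()
    derivations = _cycle_kr_derivation()
    derived = {name for name, _ in derivations}
    half = spec.log10_range / 2.0

    def log_jitter(value: float) -> float:
        return value * 10.0 ** rng.uniform(-half, half)

    sets: list[ParameterSet] = []
    for i in range(spec.n_sets):
        values = {
            name: log_jitter(v)
            for name, v in nominal.items()
            if name not in derived and not name.startswith("kcat")
        }
        for attempt in range(spec.max_resamples + 1):
            kcats = {name: log_jitter(v) for name, v in nominal.items() if name.startswith("kcat")}
            if all(kcats[hi] > kcats[lo] for hi, lo in KCAT_ORDERINGS):
                break
        else:
            raise GenerationError(
                f"could not satisfy kcat orderings after {spec.max_resamples} resamples"
            )
        values.update(kcats)
        for kr_name, (kf4, kf1, kr1, kf2, kr2, kf3, kr3) in derivations:
            k_target = (values[kf1] / values[kr1]) * (values[kf2] / values[kr2]) / (
                values[kf3] / values[kr3]
            )
            values[kr_name] = values[kf4] / k_target
        sets.append(ParameterSet(values, name=f"set{i:03d}"))
    return sets


def ensemble_to_json(ensemble: Sequence[ParameterSet], indent: int | None = 2) -> str:
    return json.dumps(
        [{"name": ps.name, "values": ps.as_dict()} for ps in ensemble], indent=indent
    )


def ensemble_from_json(text: str) -> list[ParameterSet]:
    return [ParameterSet(d["values"], name=d.get("name")) for d in json.loads(text)]


# ---------------------------------------------------------------------------
# Substrate input samples

INPUT_MODES = ("independent", "correlated_1", "correlated_r", "fixed_ratio")


@dataclass(frozen=True)
class InputSample:
    """n rows of (AA0, AG0) initial substrate concentrations in uM."""

    pairs: np.ndarray
    mode: str
    seed: int
    r_target: float | None = None
    ratio: float | None = None

    @property
    def n(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["AA0", "AG0"])

    def pearson_r(self) -> float:
        return float(np.corrcoef(self.pairs[:, 0], self.pairs[:, 1])[0, 1])


def sample_inputs(
    mode: str,
    n: int = 500,
    seed: int = 0,
    r_target: float | None = None,
    ratio: float | None = None,
    upper: float = 16.0,
) -> InputSample:
    """Sample substrate input pairs on [0, ``upper``] uM under one regime.

    ``independent``: two independent uniforms.  ``correlated_1``: AA uniform,
    AG identical (Pearson r exactly 1).  ``correlated_r``: Gaussian copula
    with uniform marginals; the normal correlation is chosen in closed form
    (``rho = 2 sin(pi r / 6)``) so the population Pearson coefficient of the
    uniforms equals ``r_target``.  ``fixed_ratio``: AG uniform on the largest
    interval keeping AA = ratio * AG within range.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}; expected one of {INPUT_MODES}")
    rng = np.random.default_rng(seed)
    if mode == "independent":
        pairs = rng.uniform(0.0, upper, size=(n, 2))
    elif mode == "correlated_1":
        aa = rng.uniform(0.0, upper, size=n)
        pairs = np.column_stack([aa, aa])
    elif mode == "correlated_r":
        if r_target is None:
            raise ValueError("correlated_r mode requires r_target")
        if not -1.0 < r_target < 1.0:
            raise ValueError("r_target must lie strictly within (-1, 1)")
        from scipy.stats import norm

        # Gaussian copula; the normal correlation is bisected so the REALIZED
        # sample Pearson coefficient of the uniform marginals hits the target.
        z1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)

        def realized(a: float) -> float:
            z2 = a * z1 + math.sqrt(1.0 - a * a) * e2
            u1, u2 = norm.cdf(z1), norm.cdf(z2)
            return float(np.corrcoef(u1, u2)[0, 1])

        lo, hi = -0.9999, 0.9999
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if realized(mid) < r_target:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
        z2 = a * z1 + math.sqrt(1.0 - a * a) * e2
        pairs = np.column_stack([norm.cdf(z1), norm.cdf(z2)]) * upper
    else:  # fixed_ratio
        if ratio is None:
            ratio = 2.0
        if ratio <= 0:
            raise ValueError("ratio must be > 0")
        ag_upper = min(upper, upper / ratio)
        ag = rng.uniform(0.0, ag_upper, size=n)
        pairs = np.column_stack([ratio * ag, ag])
    return InputSample(pairs, mode, seed, r_target=r_target, ratio=ratio)


# ---------------------------------------------------------------------------
# Toy flux graphs (test fixtures with hand-computable decompositions)

TOY_GRAPH_NAMES = ("chain", "symmetric-branch", "5-node-asymmetric", "random-DAG")


def make_toy_flux_graph(name: str, seed: int | None = None) -> FluxGraph:
    """Small flux graphs with known path decompositions.

    ``random-DAG`` (or a string like ``"random-DAG(seed=7)"``) builds a random
    layered DAG over at most 8 nodes with a single source and
    product-releasing terminal edges, for oracle comparison tests.
    """
    if name.startswith("random-DAG(") and name.endswith(")"):
        inner = name[len("random-DAG("): -1]
        if inner.startswith("seed="):
            seed = int(inner[len("seed="):])
            name = "random-DAG"
    if name == "chain":
        edges = (
            FluxEdge("S", "A", 5.0, "net_binding", ("bA",)),
            FluxEdge("A", "S", 5.0, "turnover", ("tA",), "P"),
        )
        return FluxGraph(("S", "A"), edges, source="S")
    if name == "symmetric-branch":
        edges = (
            FluxEdge("S", "A", 5.0, "net_binding", ("bA",)),
            FluxEdge("S", "B", 5.0, "net_binding", ("bB",)),
            FluxEdge("A", "S", 5.0, "turnover", ("tA",), "P"),
            FluxEdge("B", "S", 5.0, "turnover", ("tB",), "P"),
        )
        return FluxGraph(("S", "A", "B"), edges, source="S")
    if name == "5-node-asymmetric":
        edges = (
            FluxEdge("S", "A", 10.0, "net_binding", ("bA",)),
            FluxEdge("S", "B", 6.0, "net_binding", ("bB",)),
            FluxEdge("A", "C", 4.0, "net_binding", ("bAC",)),
            FluxEdge("B", "C", 3.0, "net_binding", ("bBC",)),
            FluxEdge("C", "R", 3.0, "turnover", ("tC",), "P"),
        )
        return FluxGraph(("S", "A", "B", "C", "R"), edges, source="S")
    if name == "random-DAG":
        if seed is None:
            raise ValueError("random-DAG fixture requires a seed")
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(4, 9))
        names = [f"N{i}" for i in range(n_nodes)]
        edges: list[FluxEdge] = []
        for j in range(1, n_nodes):
            # guarantee reachability: at least one inbound edge from earlier node
            parents = [i for i in range(j) if i == 0 or rng.random() < 0.5]
            if not parents:
                parents = [int(rng.integers(0, j))]
            for i in parents:
                flux = float(np.round(rng.uniform(1.0, 10.0), 3))
                edges.append(FluxEdge(names[i], names[j], flux, "net_binding", (f"b{i}_{j}",)))
        # terminal turnover edges leave the last two nodes toward a sink.
        for j in range(max(1, n_nodes - 2), n_nodes):
            flux = float(np.round(rng.uniform(1.0, 10.0), 3))
            edges.append(FluxEdge(names[j], "SINK", flux, "turnover", (f"t{j}",), "P"))
        return FluxGraph(tuple(names) + ("SINK",), tuple(edges), source=names[0])
    raise ValueError(f"unknown toy graph {name!r}; expected one of {TOY_GRAPH_NAMES}")
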