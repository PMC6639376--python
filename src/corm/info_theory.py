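"""Mutual information, response entropy, and channel-capacity estimation.

Responses are deterministic functions of the sampled substrate inputs, so all
randomness enters through the input sample.  Capacity is estimated on binned
data: inputs are quantile-binned, the empirical conditional P(y|x) is formed,
and Blahut-Arimoto iteration maximizes mutual information over the input-bin
distribution.  Finite-sample bias is corrected by subsample extrapolation
(capacity regressed linearly on inverse sample size; the intercept is the
corrected estimate), and the response-bin count is swept, keeping the largest
corrected value.  Every estimate is a lower bound on the true capacity.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corm_model import ReactionNetwork
from .kinetics import (
    CompiledNetwork,
    InitialCondition,
    IntegrationError,
    ParameterSet,
    simulate,
    steady_state_snapshot,
)
from . import synthetic_data

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTable",
    "JointHistogram",
    "CapacityEstimate",
    "dose_response",
    "build_joint_histogram",
    "mutual_information",
    "marginal_entropy",
    "response_entropy",
    "blahut_arimoto",
    "channel_capacity",
    "quadrant_capacities",
    "capacity_ensemble_sweep",
    "DEFAULT_NY_SWEEP",
    "QUADRANT_SPLIT",
]

DEFAULT_NY_SWEEP: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
QUADRANT_SPLIT = 8.0  # uM; low = [0, 8), high = [8, 16]


@dataclass(frozen=True)
class ResponseTable:
    """Deterministic 10-s responses for a table of (AA0, AG0) inputs.

    ``frame`` holds AA0, AG0, the eight complex concentrations at ``t`` and
    the cumulative PG / PGG amounts at ``t`` (one column per response).
    """

    frame: pd.DataFrame
    params_id: str
    t: float = 10.0
    response_columns: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.frame)


def dose_response(
    network: ReactionNetwork,
    params: ParameterSet,
    inputs: np.ndarray | Sequence[tuple[float, float]],
    *,
    E0: float = 0.015,
    T: float = 10.0,
    n_points: int = 21,
    compiled: CompiledNetwork | None = None,
    **sim_kwargs,
) -> ResponseTable:
    """One simulation per input row; responses snapshot at ``T`` seconds.

    Inputs outside [0, 16] uM are warned about but simulated anyway.
    Integrator failures are re-raised with the offending row index.
    """
    pairs = np.asarray(inputs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("inputs must be an (n, 2) array of (AA0, AG0)")
    if np.any((pairs < 0) | (pairs > 16.0)):
        logger.warning("some inputs fall outside [0, 16] uM")
    comp = compiled if compiled is not None else CompiledNetwork(network)
    responses = list(network.complex_ids) + ["PG", "PGG"]
    rows = []
    for i, (aa, ag) in enumerate(pairs):
        try:
            traj = simulate(
                network,
                params,
                InitialCondition(E0, aa, ag),
                T=T,
                n_points=n_points,
                compiled=comp,
                **sim_kwargs,
            )
        except IntegrationError as exc:
            raise IntegrationError(f"input row {i} (AA0={aa}, AG0={ag}): {exc}") from exc
        snap = steady_state_snapshot(traj, t=T)
        rows.append([aa, ag] + [snap[name] for name in responses])
    frame = pd.DataFrame(rows, columns=["AA0", "AG0"] + responses)
    return ResponseTable(frame, params.name or "unnamed", t=T, response_columns=tuple(responses))


# ---------------------------------------------------------------------------
# Histograms and plug-in information quantities


@dataclass(frozen=True)
class JointHistogram:
    """Joint counts over binned (input, response) symbols."""

    counts: np.ndarray  # (n_x_bins, n_y_bins)
    x_edges: np.ndarray | None = None
    y_edges: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _quantile_symbols(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency bin assignment.

    Discrete columns with at most ``n_bins`` distinct values are factorized
    (one symbol per value) rather than quantile-binned, which would merge
    heavily tied levels into a single bin.
    """
    uniq = np.unique(values)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, values).astype(np.intp), uniq
    edges = np.unique(np.quantile(values, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 2:  # constant column
        return np.zeros(len(values), dtype=np.intp), edges
    symbols = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)
    return symbols.astype(np.intp), edges


def build_joint_histogram(x: np.ndarray, y: np.ndarray, n_x: int, n_y: int) -> JointHistogram:
    """Quantile-bin both variables and tabulate joint counts."""
    xs, x_edges = _quantile_symbols(np.asarray(x, dtype=float), n_x)
    ys, y_edges = _quantile_symbols(np.asarray(y, dtype=float), n_y)
    counts = _joint_counts(xs, ys)
    return JointHistogram(counts, x_edges, y_edges)


def _joint_counts(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    nx = int(xs.max()) + 1 if len(xs) else 1
    ny = int(ys.max()) + 1 if len(ys) else 1
    counts = np.zeros((nx, ny))
    np.add.at(counts, (xs, ys), 1.0)
    return counts


def mutual_information(hist: JointHistogram | np.ndarray) -> float:
    """Plug-in estimate of I(X;Y) in bits from joint counts."""
    counts = hist.counts if isinstance(hist, JointHistogram) else np.asarray(hist, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("histogram is empty")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def marginal_entropy(counts: np.ndarray) -> float:
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def response_entropy(
    responses: np.ndarray, y_bins: int | np.ndarray = 32, scheme: str = "quantile"
) -> float:
    """H(Y) in bits of a binned response column.

    ``y_bins`` is either a bin count or an explicit edge array (the latter
    allows comparing entropies across sampling regimes on a common grid).
    ``scheme`` selects equal-frequency (``"quantile"``, consistent with the
    capacity estimator's binning) or equal-width (``"width"``) bins when a
    count is given.  A constant column has zero entropy.
    """
    values = np.asarray(responses, dtype=float)
    if len(values) == 0:
        raise ValueError("empty response column")
    if np.isscalar(y_bins) or np.ndim(y_bins) == 0:
        lo, hi = float(values.min()), float(values.max())
        if hi <= lo:
            return 0.0
        if scheme == "quantile":
            ys, _ = _quantile_symbols(values, int(y_bins))
            return marginal_entropy(np.bincount(ys))
        if scheme != "width":
            raise ValueError(f"unknown binning scheme {scheme!r}")
        edges = np.linspace(lo, hi, int(y_bins) + 1)
    else:
        edges = np.asarray(y_bins, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    return marginal_entropy(counts[counts > 0])


# ---------------------------------------------------------------------------
# Blahut-Arimoto capacity


def blahut_arimoto(
    conditional: np.ndarray,
    rel_tol: float = 1e-6,
    max_iter: int = 10_000,
    return_trace: bool = False,
):
    """Maximize I over the input distribution for a conditional P(y|x).

    Returns ``(capacity_bits, iterations)`` or, with ``return_trace``, also
    the per-iteration lower-bound sequence (non-decreasing).  Convergence is
    declared when the capacity upper/lower bound gap falls below ``rel_tol``
    (relative, with a 1e-12 absolute floor).
    """
    q_yx = np.asarray(conditional, dtype=float)
    if q_yx.ndim != 2:
        raise ValueError("conditional must be 2-D (n_x, n_y)")
    row_sums = q_yx.sum(axis=1)
    keep = row_sums > 0
    q_yx = q_yx[keep] / row_sums[keep, None]
    nx = q_yx.shape[0]
    if nx == 0:
        raise ValueError("conditional has no populated input rows")
    p = np.full(nx, 1.0 / nx)
    logq = np.where(q_yx > 0, np.log(np.where(q_yx > 0, q_yx, 1.0)), 0.0)
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        q_y = p @ q_yx
        with np.errstate(divide="ignore", invalid="ignore"):
            log_qy = np.where(q_y > 0, np.log(q_y), 0.0)
        d = np.sum(q_yx * (logq - log_qy), axis=1)  # nats
        c = np.exp(d)
        s = float(p @ c)
        lower = np.log(s)
        upper = float(np.max(d))
        trace.append(lower / np.log(2.0))
        if upper - lower <= max(rel_tol * abs(lower), 1e-12):
            break
        p = p * c / s
    capacity = trace[-1] if trace else 0.0
    capacity = max(capacity, 0.0)
    if return_trace:
        return capacity, it, np.array(trace)
    return capacity, it


@dataclass(frozen=True)
class CapacityEstimate:
    """A (lower-bound) channel-capacity estimate in bits, with metadata."""

    value: float
    channel: tuple[str, str]
    n_x_bins: int
    n_y_bins: int
    raw_value: float
    plugin_mi: float
    optimizer_iterations: int
    bias_correction: dict | None = None
    flags: tuple[str, ...] = ()
    n: int = 0


def _input_symbols(
    frame: pd.DataFrame, input_spec: str, n_x: int, n_x_joint: int
) -> tuple[np.ndarray, int]:
    if input_spec in ("AA", "AG"):
        xs, edges = _quantile_symbols(frame[f"{input_spec}0"].to_numpy(), n_x)
        return xs, max(len(edges) - 1, 1)
    if input_spec == "joint":
        xa, ea = _quantile_symbols(frame["AA0"].to_numpy(), n_x_joint)
        xg, eg = _quantile_symbols(frame["AG0"].to_numpy(), n_x_joint)
        width = max(len(eg) - 1, 1)
        return xa * width + xg, max(len(ea) - 1, 1) * width
    raise ValueError(f"unknown input_spec {input_spec!r}; expected 'AA', 'AG' or 'joint'")


def _capacity_once(xs: np.ndarray, y: np.ndarray, n_y: int, ba_tol: float) -> tuple[float, float, int]:
    """(capacity, plug-in MI, iterations) for one binning of one sample."""
    ys, y_edges = _quantile_symbols(y, n_y)
    counts = _joint_counts(xs, ys)
    if counts.shape[1] < 2:
        return 0.0, 0.0, 0
    cap, iters = blahut_arimoto(counts, rel_tol=ba_tol)
    return cap, mutual_information(counts), iters


def channel_capacity(
    table: ResponseTable,
    input_spec: str,
    response: str,
    *,
    n_x: int = 25,
    n_x_joint: int = 5,
    n_y_values: Sequence[int] = DEFAULT_NY_SWEEP,
    bias_correction: bool = True,
    subsample_fractions: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_replicates: int = 10,
    seed: int = 0,
    ba_tol: float = 1e-6,
) -> CapacityEstimate:
    """Estimate the channel capacity from an input spec to one response column.

    The focal input(s) are quantile-binned (``n_x`` bins, or ``n_x_joint`` per
    axis for the joint input) and the response is quantile-binned for each
    value in ``n_y_values``.  Blahut-Arimoto gives the per-binning capacity;
    subsample extrapolation (linear in 1/m) removes finite-sample bias, and
    the maximum corrected value over the sweep is reported.  A constant
    response yields capacity 0 with a ``degenerate_response`` flag.
    """
    frame = table.frame
    n = len(frame)
    if n < 50:
        raise ValueError(f"need at least 50 rows, got {n}")
    if response not in frame.columns:
        raise KeyError(f"response column {response!r} not in table")
    y = frame[response].to_numpy(dtype=float)
    xs_full, nx_eff = _input_symbols(frame, input_spec, n_x, n_x_joint)

    if np.all(y == y[0]):
        return CapacityEstimate(
            value=0.0,
            channel=(input_spec, response),
            n_x_bins=nx_eff,
            n_y_bins=0,
            raw_value=0.0,
            plugin_mi=0.0,
            optimizer_iterations=0,
            flags=("degenerate_response",),
            n=n,
        )

    rng = np.random.default_rng(seed)
    best: CapacityEstimate | None = None
    for n_y in n_y_values:
        raw, plugin, iters = _capacity_once(xs_full, y, n_y, ba_tol)
        meta = None
        value = raw
        if bias_correction:
            inv_m, caps = [], []
            for frac in subsample_fractions:
                m = max(2, int(round(frac * n)))
                if m >= n:
                    inv_m.append(1.0 / n)
                    caps.append(raw)
                    continue
                reps = []
                for _ in range(n_replicates):
                    idx = rng.choice(n, size=m, replace=False)
                    cap_m, _, _ = _capacity_once(xs_full[idx], y[idx], n_y, ba_tol)
                    reps.append(cap_m)
                inv_m.append(1.0 / m)
                caps.append(float(np.mean(reps)))
            slope, intercept = np.polyfit(inv_m, caps, 1)
            value = float(np.clip(intercept, 0.0, np.log2(n)))
            meta = {
                "subsample_fractions": tuple(subsample_fractions),
                "n_replicates": n_replicates,
                "intercept": float(intercept),
                "slope": float(slope),
                "seed": seed,
            }
        if best is None or value > best.value:
            best = CapacityEstimate(
                value=value,
                channel=(input_spec, response),
                n_x_bins=nx_eff,
                n_y_bins=n_y,
                raw_value=raw,
                plugin_mi=plugin,
                optimizer_iterations=iters,
                bias_correction=meta,
                n=n,
            )
    assert best is not None
    return best


def quadrant_capacities(
    table: ResponseTable,
    response: str,
    input_spec: str = "joint",
    min_rows: int = 50,
    **estimator_kwargs,
) -> dict[tuple[str, str], CapacityEstimate]:
    """Capacity per (AA level, AG level) quadrant; low = [0, 8), high = [8, 16]."""
    frame = table.frame
    out: dict[tuple[str, str], CapacityEstimate] = {}
    for aa_level in ("low", "high"):
        for ag_level in ("low", "high"):
            mask = np.ones(len(frame), dtype=bool)
            aa, ag = frame["AA0"].to_numpy(), frame["AG0"].to_numpy()
            mask &= (aa < QUADRANT_SPLIT) if aa_level == "low" else (aa >= QUADRANT_SPLIT)
            mask &= (ag < QUADRANT_SPLIT) if ag_level == "low" else (ag >= QUADRANT_SPLIT)
            sub = ResponseTable(
                frame[mask].reset_index(drop=True),
                table.params_id,
                t=table.t,
                response_columns=table.response_columns,
            )
            if sub.n < min_rows:
                est = CapacityEstimate(
                    value=float("nan"),
                    channel=(input_spec, response),
                    n_x_bins=0,
                    n_y_bins=0,
                    raw_value=float("nan"),
                    plugin_mi=float("nan"),
                    optimizer_iterations=0,
                    flags=("unreliable_few_rows",),
                    n=sub.n,
                )
            else:
                est = channel_capacity(sub, input_spec, response, **estimator_kwargs)
            out[(aa_level, ag_level)] = est
    return out


def _stable_subseed(seed: int, *parts: str) -> int:
    digest = hashlib.sha256(("|".join(map(str, parts)) + f"|{seed}").encode()).digest()
    return int.from_bytes(digest[:4], "big")


def capacity_ensemble_sweep(
    network: ReactionNetwork,
    ensemble: Sequence[ParameterSet],
    input_mode: str,
    *,
    responses: Sequence[str] | None = None,
    input_specs: Sequence[str] = ("AA",),
    n_samples: int = 500,
    seed: int = 0,
    r_target: float | None = None,
    ratio: float | None = None,
    quadrants: bool = False,
    E0: float = 0.015,
    T: float = 10.0,
    **estimator_kwargs,
) -> pd.DataFrame:
    """Capacity estimates per parameter set for every requested response.

    One input sample (per ``input_mode``/``seed``) is shared across the whole
    ensemble so that parameter sets are compared on identical inputs.
    Integrator failures skip the parameter set and are counted in
    ``result.attrs['n_failed']``.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    sample = synthetic_data.sample_inputs(
        input_mode, n=n_samples, seed=seed, r_target=r_target, ratio=ratio
    )
    if responses is None:
        responses = list(network.complex_ids) + ["PG", "PGG"]
    comp = CompiledNetwork(network)
    rows = []
    n_failed = 0
    for i, params in enumerate(ensemble):
        params_id = params.name or f"set{i:03d}"
        try:
            table = dose_response(
                network, params, sample.pairs, E0=E0, T=T, compiled=comp
            )
        except IntegrationError as exc:
            logger.warning("skipping %s: %s", params_id, exc)
            n_failed += 1
            continue
        for input_spec in input_specs:
            for response in responses:
                sub_seed = _stable_subseed(seed, params_id, input_spec, response)
                est = channel_capacity(
                    table, input_spec, response, seed=sub_seed, **estimator_kwargs
                )
                quads: dict = {("all", "all"): est}
                if quadrants:
                    quads.update(
                        quadrant_capacities(
                            table, response, input_spec=input_spec,
                            seed=sub_seed, **estimator_kwargs,
                        )
                    )
                for (aa_level, ag_level), q_est in quads.items():
                    rows.append(
                        {
                            "params_id": params_id,
                            "input_spec": input_spec,
                            "response": response,
                            "mode": input_mode,
                            "quadrant": (
                                "all" if aa_level == "all" else f"AA_{aa_level}|AG_{ag_level}"
                            ),
                            "capacity_bits": q_est.value,
                            "raw_capacity_bits": q_est.raw_value,
                            "plugin_mi_bits": q_est.plugin_mi,
                            "n_x": q_est.n_x_bins,
                            "n_y": q_est.n_y_bins,
                            "bias_intercept": (
                                q_est.bias_correction["intercept"]
                                if q_est.bias_correction
                                else float("nan")
                            ),
                            "flags": ";".join(q_est.flags),
                            "seed": sub_seed,
                            "n": q_est.n,
                        }
                    )
    result = pd.DataFrame(rows)
    result.attrs["n_failed"] = n_failed
    result.attrs["input_mode"] = input_mode
    result.attrs["seed"] = seed
    return result
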