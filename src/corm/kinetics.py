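"""Deterministic mass-action kinetics: ODE integration and flux recording.

Integrates the reaction network with a stiff-capable solver and records both
species concentrations and instantaneous per-reaction rates on a dense time
grid, so that downstream flux quadrature never re-solves the system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .corm_model import FREE_ENZYME_ID, ReactionNetwork, binding_cycles

__all__ = [
    "ParameterSet",
    "InitialCondition",
    "Trajectory",
    "IntegrationError",
    "CompiledNetwork",
    "simulate",
    "steady_state_snapshot",
    "cycle_ratios",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message names the offending parameter set."""


@dataclass(frozen=True)
class ParameterSet:
    """Named rate constants: 12 kf (1/(uM s)), 12 kr (1/s), 5 kcat (1/s)."""

    values: Mapping[str, float]
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def get(self, key: str, default: float | None = None):
        return self.values.get(key, default)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def validate(self, network: ReactionNetwork, cycle_rtol: float = 1e-6) -> None:
        """Check completeness, non-negativity and thermodynamic cycle closure."""
        for name in network.parameter_names:
            if name not in self.values:
                raise KeyError(f"missing rate constant {name!r}")
        for name, value in self.values.items():
            if value < 0:
                raise ValueError(f"negative rate constant {name}={value}")
        for cyc, ratio in zip(binding_cycles(), cycle_ratios(self)):
            if not np.isclose(ratio, 1.0, rtol=cycle_rtol, atol=0.0):
                raise ValueError(
                    "thermodynamic cycle not closed for "
                    f"cat={cyc['cat_ligand']}, allo={cyc['allo_ligand']}: ratio={ratio}"
                )


def cycle_ratios(params: ParameterSet | Mapping[str, float]) -> list[float]:
    """K-product ratios of the four binding cycles; all 1.0 under detailed balance."""
    ratios = []
    for cyc in binding_cycles():
        num = 1.0
        for kf, kr in cyc["numerator"]:
            num *= params[kf] / params[kr]
        den = 1.0
        for kf, kr in cyc["denominator"]:
            den *= params[kf] / params[kr]
        ratios.append(num / den)
    return ratios


@dataclass(frozen=True)
class InitialCondition:
    """Initial mix: free enzyme plus free substrates; everything else at zero."""

    E0: float = 0.015  # uM; placeholder for an in-vitro assay scale, configurable
    AA0: float = 0.0
    AG0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E0", "AA0", "AG0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class CompiledNetwork:
    """Index-array form of a network for fast vectorized rate evaluation."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.species_ids = [sp.id for sp in network.species]
        self.reaction_ids = [rx.id for rx in network.reactions]
        self.param_names = [rx.rate_constant_ref for rx in network.reactions]
        index = {sid: i for i, sid in enumerate(self.species_ids)}
        n_s, n_r = len(self.species_ids), len(self.reaction_ids)

        first = np.empty(n_r, dtype=np.intp)
        second = np.full(n_r, -1, dtype=np.intp)
        stoich = np.zeros((n_s, n_r))
        for j, rx in enumerate(network.reactions):
            reactant_idx = []
            for sid, count in rx.reactants:
                stoich[index[sid], j] -= count
                reactant_idx.extend([index[sid]] * count)
            for sid, count in rx.products:
                stoich[index[sid], j] += count
            if not 1 <= len(reactant_idx) <= 2:
                raise ValueError(f"reaction {rx.id} is not uni- or bimolecular")
            first[j] = reactant_idx[0]
            if len(reactant_idx) == 2:
                second[j] = reactant_idx[1]
        self.first = first
        self.second = second
        self.has_second = second >= 0
        self.stoich = stoich
        self.index = index

    def param_vector(self, params: ParameterSet | Mapping[str, float]) -> np.ndarray:
        return np.array([params[name] for name in self.param_names])

    def rates(self, conc: np.ndarray, k: np.ndarray) -> np.ndarray:
        r = k * conc[..., self.first]
        r = np.where(self.has_second, r * conc[..., np.maximum(self.second, 0)], r)
        return r

    def rhs(self, t: float, conc: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(conc, k)

    def jacobian(self, t: float, conc: np.ndarray, k: np.ndarray) -> np.ndarray:
        n_r, n_s = len(self.reaction_ids), len(self.species_ids)
        d_rates = np.zeros((n_r, n_s))
        rows = np.arange(n_r)
        other = np.where(self.has_second, conc[np.maximum(self.second, 0)], 1.0)
        np.add.at(d_rates, (rows, self.first), k * other)
        rows2 = rows[self.has_second]
        np.add.at(d_rates, (rows2, self.second[self.has_second]), k[self.has_second] * conc[self.first[self.has_second]])
        return self.stoich @ d_rates


@dataclass
class Trajectory:
    """Concentrations (uM) and instantaneous reaction rates (uM/s) on a grid."""

    times: np.ndarray
    species_ids: list[str]
    conc: np.ndarray  # (n_points, n_species)
    reaction_ids: list[str]
    rates: np.ndarray  # (n_points, n_reactions)

    def conc_of(self, species_id: str) -> np.ndarray:
        return self.conc[:, self.species_ids.index(species_id)]

    def rate_of(self, reaction_id: str) -> np.ndarray:
        return self.rates[:, self.reaction_ids.index(reaction_id)]

    def conc_at(self, t: float) -> dict[str, float]:
        """Species concentrations at time ``t``, interpolated on the grid."""
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(f"t={t} outside trajectory window [{self.times[0]}, {self.times[-1]}]")
        return {
            sid: float(np.interp(t, self.times, self.conc[:, i]))
            for i, sid in enumerate(self.species_ids)
        }

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.conc, columns=self.species_ids)
        for i, rid in enumerate(self.reaction_ids):
            frame[f"rate:{rid}"] = self.rates[:, i]
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path_or_buf, **kwargs) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, **kwargs)


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    init: InitialCondition,
    T: float = 10.0,
    n_points: int = 2001,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    y0: np.ndarray | None = None,
    compiled: CompiledNetwork | None = None,
) -> Trajectory:
    """Integrate the ODE system on a uniform grid over ``[0, T]``.

    ``y0`` optionally overrides the full initial state vector (species order
    of the network); otherwise the state is assembled from ``init``.
    Deterministic given identical inputs.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    comp = compiled if compiled is not None else CompiledNetwork(network)
    k = comp.param_vector(params)
    if y0 is None:
        y0 = np.zeros(len(comp.species_ids))
        y0[comp.index[FREE_ENZYME_ID]] = init.E0
        y0[comp.index["AA"]] = init.AA0
        y0[comp.index["AG"]] = init.AG0
    else:
        y0 = np.asarray(y0, dtype=float)

    times = np.linspace(0.0, T, n_points)
    sol = solve_ivp(
        comp.rhs,
        (0.0, T),
        y0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=comp.jacobian,
        args=(k,),
    )
    if not sol.success:
        label = params.name or "unnamed parameter set"
        raise IntegrationError(f"ODE integration failed for {label}: {sol.message}")
    conc = sol.y.T
    rates = comp.rates(conc, k)
    return Trajectory(times, list(comp.species_ids), conc, list(comp.reaction_ids), rates)


def steady_state_snapshot(traj: Trajectory, t: float = 10.0) -> dict[str, float]:
    """All species concentrations at time ``t`` (default 10 s).

    Products accumulate as ordinary species, so their entries are the
    cumulative amounts formed by ``t``.  Raises if the trajectory is shorter
    than ``t``.
    """
    if traj.times[-1] < t - 1e-9:
        raise ValueError(f"trajectory ends at {traj.times[-1]} s, before t={t} s")
    return traj.conc_at(t)
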