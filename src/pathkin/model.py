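"""Model/Results front end for network kinetics.

:class:`NetworkKinetics` is built from a :class:`ReactionPathNetwork` plus
run settings; ``fit()`` propagates the master equation (exactly or via
rate-constant-matrix contraction) and returns a
:class:`NetworkKineticsResults` carrying the endpoint populations, the
trajectory, traffic volumes, the contraction audit trail and a ``summary()``
table.  Selectivity is evaluated on the results against a group assignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics as _kin
from .grouping import GroupAssignment
from .network import ReactionPathNetwork, read_network
from .rates import RateMatrix, build_rate_matrix
from .selectivity import SelectivityResult, aggregate_yields

__all__ = ["NetworkKinetics", "NetworkKineticsResults"]

#: two days at the experimental 60 °C, in seconds
DEFAULT_T_FINAL = 172_800.0


class NetworkKinetics:
    """First-order kinetics model on a reaction path network.

    Parameters
    ----------
    network : ReactionPathNetwork
        Validated network; its temperature sets the Eyring rates.
    t_final : float, default 172800
        Simulated reaction time in s (two days).
    rate_threshold : float, optional
        Contraction rate scale in s⁻¹ for the RCMC solver; default
        1/t_final.
    initial : mapping, array or None
        Initial populations: a node-id→population mapping, a vector over
        the node order, or None for a Boltzmann distribution over
        ``reactant_nodes`` (over all nodes if those are not given).
    reactant_nodes : sequence of node ids, optional
        The reactant conformer ensemble used for the default initial state.
    """

    def __init__(
        self,
        network: ReactionPathNetwork,
        *,
        t_final: float = DEFAULT_T_FINAL,
        rate_threshold: float | None = None,
        initial: Mapping[str, float] | np.ndarray | None = None,
        reactant_nodes: Sequence[str] | None = None,
        points_per_decade: int = 200,
    ) -> None:
        self.network = network
        self.t_final = float(t_final)
        self.rate_threshold = rate_threshold
        self.points_per_decade = points_per_decade
        self.rate_matrix: RateMatrix = build_rate_matrix(network)
        self.reactant_nodes = list(reactant_nodes) if reactant_nodes else None
        if initial is None:
            self._p0 = _kin.boltzmann_state(self.rate_matrix, self.reactant_nodes)
        elif isinstance(initial, Mapping):
            p = np.zeros(self.rate_matrix.size)
            for nid, val in initial.items():
                p[self.rate_matrix.index[nid]] = val
            total = p.sum()
            if total <= 0:
                raise ValueError("initial populations sum to 0")
            self._p0 = _kin.KineticState(p / total, 0.0, list(self.rate_matrix.node_order))
        else:
            self._p0 = _kin.KineticState(
                np.asarray(initial, float), 0.0, list(self.rate_matrix.node_order)
            )

    @classmethod
    def from_tables(
        cls,
        nodes_table: str | Path,
        edges_table: str | Path,
        temperature: float = 333.15,
        **kwargs,
    ) -> "NetworkKinetics":
        """Build the model straight from the on-disk nodes/edges CSV tables."""
        return cls(read_network(nodes_table, edges_table, temperature), **kwargs)

    @property
    def initial_state(self) -> _kin.KineticState:
        return self._p0

    def fit(self, method: str = "rcmc", safety: float = 1e10) -> "NetworkKineticsResults":
        """Propagate to ``t_final``.

        method="rcmc" contracts fast states first (the production route for
        stiff networks); method="exact" propagates the full master equation
        and is the small-network reference.
        """
        if method == "rcmc":
            state, record = _kin.rcmc_solve(
                self.rate_matrix,
                self._p0,
                self.t_final,
                rate_threshold=self.rate_threshold,
                safety=safety,
                points_per_decade=self.points_per_decade,
            )
            trajectory = record.trajectory
        elif method == "exact":
            trajectory = _kin.simulate(
                self.rate_matrix, self._p0, self.t_final, self.points_per_decade
            )
            state, record = trajectory.final, None
        else:
            raise ValueError(f"unknown method {method!r} (use 'rcmc' or 'exact')")
        return NetworkKineticsResults(self, method, state, trajectory, record)


class NetworkKineticsResults:
    """Endpoint populations, trajectory, traffic volumes and diagnostics."""

    def __init__(self, model, method, state, trajectory, record):
        self.model: NetworkKinetics = model
        self.method: str = method
        self.state: _kin.KineticState = state
        self.trajectory: _kin.KineticTrajectory = trajectory
        self.record: _kin.ContractionRecord | None = record
        self._traffic: _kin.TrafficVolumes | None = None

    @property
    def populations(self) -> pd.Series:
        return self.state.as_series()

    @property
    def traffic(self) -> _kin.TrafficVolumes:
        if self._traffic is None:
            self._traffic = _kin.traffic_volume(self.model.rate_matrix, self.trajectory)
        return self._traffic

    def group_populations(self, assignment: GroupAssignment | Mapping[str, str]) -> pd.Series:
        node_to_group = (
            assignment.node_to_group
            if isinstance(assignment, GroupAssignment)
            else assignment
        )
        return self.populations.groupby(
            pd.Series({n: node_to_group[n] for n in self.populations.index})
        ).sum()

    def selectivity(
        self,
        assignment: GroupAssignment | Mapping[str, str],
        product_groups_s: Sequence[str],
        product_groups_r: Sequence[str],
    ) -> SelectivityResult:
        node_to_group = (
            assignment.node_to_group
            if isinstance(assignment, GroupAssignment)
            else assignment
        )
        return aggregate_yields(
            self.state,
            node_to_group,
            product_groups_s,
            product_groups_r,
            self.model.network.temperature,
        )

    def edge_fluxes(self) -> pd.DataFrame:
        return _kin.integrated_edge_flux(
            self.model.network, self.model.rate_matrix, self.trajectory
        )

    def summary(self, top: int = 8) -> str:
        m = self.model
        lines = [
            "Network kinetics results",
            "=" * 54,
            f"nodes: {m.network.n_nodes}   paths: {m.network.n_edges}   "
            f"T: {m.network.temperature:g} K",
            f"method: {self.method}   t_final: {m.t_final:g} s",
            f"population conservation: {self.state.populations.sum():.12f}",
        ]
        if self.record is not None:
            lines.append(
                f"contracted states: {self.record.n_contracted} / {m.network.n_nodes}"
                f"   rate threshold: {self.record.rate_threshold:g} s^-1"
            )
        pops = self.populations.sort_values(ascending=False).head(top)
        lines.append("-" * 54)
        lines.append(f"top {top} populations at t_final:")
        for nid, p in pops.items():
            lines.append(f"  {nid:<24s} {p:12.6f}")
        vols = self.traffic.per_node.sort_values(ascending=False).head(top)
        lines.append(f"top {top} traffic volumes:")
        for nid, v in vols.items():
            lines.append(f"  {nid:<24s} {v:12.6g}")
        return "\n".join(lines)
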