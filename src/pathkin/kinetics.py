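"""Population kinetics on a reaction path network.

Two solvers operate on the same first-order rate matrix:

* :func:`solve_master_equation` / :func:`simulate` — the exact reference,
  p(t) = exp(K·t)·p₀, evaluated by dense matrix exponential or, on a time
  grid, by spectral decomposition (symmetrized via the Boltzmann weights when
  the matrix satisfies detailed balance).

* :func:`rcmc_solve` — a rate-constant-matrix-contraction solver for stiff
  networks: states whose total escape rate is far above the reporting rate
  scale are contracted one by one — transit states by steady-state
  elimination with branching-ratio redistribution, population-holding states
  by merging into Boltzmann-weighted superstates; the contracted
  (de-stiffened) system is then propagated exactly and full-space
  populations are reconstructed from the superstate weights and
  quasi-steady-state balance.

Both solvers produce trajectories on a logarithmic time grid from which
per-node *traffic volumes* — the time-integrated population influx plus
outflow of each EQ, a measure of kinetic importance independent of final
yield — are accumulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .constants import rt_kj
from .network import ReactionPathNetwork
from .rates import RateMatrix, eyring_rate

__all__ = [
    "KineticState",
    "KineticTrajectory",
    "ContractionStep",
    "ContractionRecord",
    "TrafficVolumes",
    "boltzmann_state",
    "delta_state",
    "time_grid",
    "solve_master_equation",
    "simulate",
    "rcmc_solve",
    "traffic_volume",
    "integrated_edge_flux",
]

_CONSERVATION_TOL = 1e-9


# ---------------------------------------------------------------------------
# states and trajectories


@dataclass
class KineticState:
    """Dimensionless populations over ``node_order`` at a time point."""

    populations: np.ndarray
    time: float
    node_order: list[str]

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.shape != (len(self.node_order),):
            raise ValueError("populations length does not match node_order")
        if self.populations.min() < -1e-12:
            raise ValueError(
                f"negative population {self.populations.min():g} at t={self.time}"
            )
        self.populations = np.clip(self.populations, 0.0, None)
        total = self.populations.sum()
        if abs(total - 1.0) > _CONSERVATION_TOL:
            raise ValueError(f"populations sum to {total}, not 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.populations, index=self.node_order, name="population")

    def __getitem__(self, node_id: str) -> float:
        return float(self.populations[self.node_order.index(node_id)])


@dataclass
class KineticTrajectory:
    """Populations on a time grid; row k is the state at ``times[k]``."""

    times: np.ndarray
    populations: np.ndarray  # (n_times, n_nodes)
    node_order: list[str]

    @property
    def final(self) -> KineticState:
        return KineticState(
            self.populations[-1], float(self.times[-1]), self.node_order
        )

    def state_at(self, k: int) -> KineticState:
        return KineticState(self.populations[k], float(self.times[k]), self.node_order)


def boltzmann_state(rm: RateMatrix, node_ids: Sequence[str] | None = None) -> KineticState:
    """Boltzmann-distributed initial populations over a subset of nodes.

    This is the natural initial condition for a pre-equilibrated reactant
    conformer ensemble.  Requires the rate matrix to carry node energies.
    """
    if rm.node_gibbs is None:
        raise ValueError("rate matrix carries no node energies")
    ids = list(node_ids) if node_ids is not None else list(rm.node_order)
    idx = [rm.index[i] for i in ids]
    g = rm.node_gibbs[idx]
    w = np.exp(-(g - g.min()) / rt_kj(rm.temperature))
    p = np.zeros(rm.size)
    p[idx] = w / w.sum()
    return KineticState(p, 0.0, list(rm.node_order))


def delta_state(rm: RateMatrix, node_id: str) -> KineticState:
    p = np.zeros(rm.size)
    p[rm.index[node_id]] = 1.0
    return KineticState(p, 0.0, list(rm.node_order))


def _as_p0(rm: RateMatrix, p0: KineticState | np.ndarray) -> np.ndarray:
    vec = p0.populations if isinstance(p0, KineticState) else np.asarray(p0, float)
    if vec.shape != (rm.size,):
        raise ValueError(
            f"initial population length {vec.shape} does not match matrix size {rm.size}"
        )
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError(f"initial populations sum to {vec.sum()}, not 1")
    return vec / vec.sum()


# ---------------------------------------------------------------------------
# propagation


def time_grid(
    t_final: float,
    max_rate: float | None = None,
    points_per_decade: int = 200,
    span_decades: float = 12.0,
) -> np.ndarray:
    """Logarithmic time grid [0, ..., t_final] resolving the fast dynamics.

    The first positive point is placed well below both ``t_final·10^-span``
    and the shortest relaxation time ``1/max_rate`` so that trapezoidal
    integrals over the grid capture the earliest transients.
    """
    if t_final < 0:
        raise ValueError("t_final must be >= 0")
    if t_final == 0:
        return np.array([0.0])
    t_min = t_final * 10.0 ** (-span_decades)
    if max_rate is not None and max_rate > 0:
        t_min = min(t_min, 0.01 / max_rate)
    n_dec = math.log10(t_final / t_min)
    n_pts = max(int(math.ceil(n_dec * points_per_decade)), 10)
    grid = np.logspace(math.log10(t_min), math.log10(t_final), n_pts + 1)
    grid[-1] = t_final
    return np.concatenate([[0.0], grid])


def _spectral_factors(rm: RateMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Symmetrized eigendecomposition when detailed balance holds.

    With Boltzmann weights w, S = D^{-1/2} K D^{1/2} is symmetric with
    off-diagonal entries sqrt(k_ij·k_ji); returns (eigenvalues, U, sqrt(w))
    or None if the matrix is not detailed-balanced.
    """
    if rm.node_gibbs is None:
        return None
    K = rm.dense()
    w = np.exp(-(rm.node_gibbs - rm.node_gibbs.min()) / rt_kj(rm.temperature))
    flux = K * w[None, :]  # flux[i, j] = k[i<-j] w_j
    asym = np.abs(flux - flux.T)
    if not (asym <= 1e-8 * (np.abs(flux) + np.abs(flux.T)) + 1e-300).all():
        return None
    off = np.sqrt(K * K.T)
    np.fill_diagonal(off, 0.0)
    S = off + np.diag(np.diag(K))
    lam, U = np.linalg.eigh(S)
    lam = np.minimum(lam, 0.0)  # the zero mode must not grow from roundoff
    return lam, U, np.sqrt(w)


def _step_expm(K: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Propagate by composing matrix exponentials between grid points."""
    P = np.empty((len(times), len(p0)))
    p = p0.copy()
    P[0] = p
    for k in range(1, len(times)):
        p = expm(K * (times[k] - times[k - 1])) @ p
        P[k] = p
    return P


def _propagate_grid(
    rm: RateMatrix, p0: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """p(t) for every t in ``times``; (n_times, n) array.

    The spectral route (detailed-balance symmetrization) is fast but loses
    reaction channels whose symmetrized coupling sqrt(k_fwd·k_rev) falls
    below the eigensolver's absolute resolution eps·||S|| (deep product
    wells do this); its endpoint is therefore validated against one direct
    matrix exponential and the propagation falls back to stepped
    exponentials when they disagree.
    """
    spectral = _spectral_factors(rm)
    if spectral is not None:
        lam, U, sq = spectral
        c = U.T @ (p0 / sq)
        # exp(lam*t) decays; clamp the exponent to avoid needless underflow warnings
        expo = np.clip(np.outer(times, lam), -745.0, 0.0)
        P = (np.exp(expo) * c[None, :]) @ U.T
        P *= sq[None, :]
        if len(times) > 1:
            p_end = expm(rm.dense() * times[-1]) @ p0
            if np.abs(np.clip(P[-1], 0.0, None) - np.clip(p_end, 0.0, None)).max() > 1e-6:
                P = _step_expm(rm.dense(), p0, times)
    else:
        K = rm.dense()
        lam, V = np.linalg.eig(K)
        use_eig = False
        if np.linalg.cond(V) < 1e8:
            lam = np.where(lam.real > 0, lam - lam.real, lam)
            c = np.linalg.solve(V, p0.astype(complex))
            expo = np.outer(times, lam)
            expo = np.where(expo.real > 0, expo - expo.real, expo)
            P = ((np.exp(expo) * c[None, :]) @ V.T).real
            use_eig = True
        if not use_eig:
            P = _step_expm(K, p0, times)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def solve_master_equation(
    rm: RateMatrix, p0: KineticState | np.ndarray, t_final: float
) -> KineticState:
    """Exact endpoint populations p(t_final) = exp(K·t_final)·p₀.

    Dense matrix exponential for n ≤ 2000; larger detailed-balanced systems
    use the spectral route.
    """
    vec = _as_p0(rm, p0)
    if t_final < 0:
        raise ValueError("t_final must be >= 0")
    if t_final == 0:
        return KineticState(vec, 0.0, list(rm.node_order))
    if rm.size <= 2000:
        p = expm(rm.dense() * t_final) @ vec
    else:
        P = _propagate_grid(rm, vec, np.array([0.0, t_final]))
        p = P[-1]
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return KineticState(p, t_final, list(rm.node_order))


def simulate(
    rm: RateMatrix,
    p0: KineticState | np.ndarray,
    t_final: float,
    points_per_decade: int = 200,
) -> KineticTrajectory:
    """Exact trajectory on a logarithmic time grid (the traffic-volume oracle)."""
    vec = _as_p0(rm, p0)
    times = time_grid(t_final, float(rm.escape_rates().max(initial=0.0)),
                      points_per_decade)
    P = _propagate_grid(rm, vec, times)
    return KineticTrajectory(times, P, list(rm.node_order))


# ---------------------------------------------------------------------------
# rate-constant-matrix contraction


@dataclass
class ContractionStep:
    node: str
    escape_rate: float
    branching: dict[str, float]
    kind: str = "eliminate"  # "eliminate" (steady-state) or "merge" (lumped)
    transit_population: float = 0.0


@dataclass
class ContractionRecord:
    """Audit trail of a contraction run.

    ``steps`` lists the eliminated nodes in contraction order with their
    escape rates, branching ratios (sum 1) and accumulated transit
    populations; ``superstates`` maps each surviving node to the contracted
    nodes whose dominant branching chain terminates on it.  The reconstructed
    full-space trajectory is attached for traffic-volume accumulation.
    """

    steps: list[ContractionStep]
    superstates: dict[str, list[str]]
    surviving: list[str]
    rate_threshold: float
    safety: float
    trajectory: KineticTrajectory | None = None
    reduced_matrix: RateMatrix | None = None

    @property
    def n_contracted(self) -> int:
        return len(self.steps)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "rate_threshold": self.rate_threshold,
            "safety": self.safety,
            "surviving": self.surviving,
            "superstates": self.superstates,
            "steps": [
                {
                    "node": s.node,
                    "escape_rate": s.escape_rate,
                    "branching": s.branching,
                    "transit_population": s.transit_population,
                }
                for s in self.steps
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def rcmc_solve(
    rm: RateMatrix,
    p0: KineticState | np.ndarray,
    t_final: float,
    rate_threshold: float | None = None,
    safety: float = 1e10,
    schur_share_tol: float = 1e-3,
    points_per_decade: int = 200,
) -> tuple[KineticState, ContractionRecord]:
    """Contract fast-escaping states, then propagate the reduced system.

    While the largest total escape rate exceeds ``safety·rate_threshold``
    (default threshold 1/t_final), that state is contracted.  Two contraction
    moves are used, chosen per state:

    * **steady-state elimination** for transit states — states whose slaved
      population share k[i←m]/Σk[·←i] is below ``schur_share_tol`` for every
      feeder m: their inflow is redistributed to the surviving neighbours by
      branching ratios k[j←i]/Σk[·←i], adding effective rates
      k[j←i]·k[i←m]/Σk[·←i]; at reporting their population is reconstructed
      from quasi-steady-state balance (inflow/escape, in reverse contraction
      order).

    * **lumping** for reservoir states — fast states that hold real
      population: the state is merged with the neighbour receiving its
      largest outflow into one superstate whose internal weights are the
      equilibrium weights implied by the exchange rates (the Boltzmann
      weights, under detailed balance).  Outflow rates of the superstate are
      the weight-averaged member rates; inflows add.  At reporting the
      superstate mass is back-distributed over its members by those weights.

    Elimination of a state holding real population misbooks that mass onto
    its neighbours (an error of the order of the slaved share, not of
    exp(−escape·t)), which is why reservoirs are lumped instead.  The safety
    factor keeps every state within ``safety`` rate decades of the reporting
    scale in the propagated system, where it is handled exactly: contraction
    removes only the stiffness the exact propagator cannot absorb.
    """
    vec = _as_p0(rm, p0).copy()
    if t_final < 0:
        raise ValueError("t_final must be >= 0")
    if rate_threshold is None:
        rate_threshold = np.inf if t_final == 0 else 1.0 / t_final
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be > 0")
    if rm.size == 0:
        raise ValueError("empty network")

    order = list(rm.node_order)
    n = rm.size
    K = rm.dense().copy()
    active = np.ones(n, dtype=bool)
    cutoff = safety * rate_threshold

    # per-superstate bookkeeping (indexed by representative = matrix index)
    if rm.node_gibbs is not None:
        rt = rt_kj(rm.temperature)
        w0 = np.exp(-(rm.node_gibbs - rm.node_gibbs.min()) / rt)
    else:
        w0 = np.ones(n)
    members: dict[int, dict[int, float]] = {i: {i: float(w0[i])} for i in range(n)}
    w_total = w0.copy()
    mass = vec  # superstate masses; starts as node populations

    steps: list[ContractionStep] = []
    # (rep, normalized member weights, per-node inflow coefficients, escape)
    schur_recon: list[tuple[int, dict[int, float], np.ndarray, float]] = []
    merge_sets: list[tuple[int, dict[int, float], float]] = []
    parent: dict[int, int] = {}

    while True:
        esc = -np.diag(K)
        esc_active = np.where(active, esc, -np.inf)
        top = esc_active.max()
        if not (top > cutoff):
            break
        # deterministic tie-break: among maximal escape rates, lowest node id
        cands = np.flatnonzero(np.isclose(esc_active, top, rtol=1e-12, atol=0.0))
        s = min(cands, key=lambda k: order[k])
        others = np.flatnonzero(active)
        others = others[others != s]
        if others.size == 0:
            break
        k_out = K[others, s].copy()
        esc_s = float(k_out.sum())
        if esc_s <= 0:  # pragma: no cover - escape>cutoff implies outflow
            break
        b = k_out / esc_s
        inflow = K[s, others].copy()
        shares = inflow / esc_s
        transit = shares.max(initial=0.0) <= schur_share_tol
        steps.append(
            ContractionStep(
                order[s],
                esc_s,
                {order[j]: float(bv) for j, bv in zip(others, b) if bv > 0.0},
                kind="eliminate" if transit else "merge",
            )
        )
        if transit:
            # per-node inflow coefficients: flux into s from superstate m is
            # K[s, m] * (sum of member populations of m)
            a = np.zeros(n)
            for m in others:
                if inflow[np.searchsorted(others, m)] > 0.0:
                    for u in members[m]:
                        a[u] = K[s, m]
            wm = members[s]
            tot = sum(wm.values())
            norm = {u: (w / tot if tot > 0 else 1.0 / len(wm)) for u, w in wm.items()}
            schur_recon.append((s, norm, a, esc_s))
            parent[s] = int(others[int(np.argmax(b))])
            # initial mass on s drains along the branching ratios
            mass[others] += b * mass[s]
            mass[s] = 0.0
            K[np.ix_(others, others)] += np.outer(b, inflow)
        else:
            # merge s into the neighbour taking its largest outflow
            cand = np.flatnonzero(np.isclose(k_out, k_out.max(), rtol=1e-12, atol=0.0))
            p = int(others[min(cand, key=lambda k: order[others[k]])])
            k_sp = K[s, p]  # p -> s
            k_ps = K[p, s]  # s -> p
            w_s_new = w_total[p] * k_sp / k_ps if k_sp > 0 else 0.0
            scale = w_s_new / w_total[s] if w_total[s] > 0 else 0.0
            for u, w in members[s].items():
                members[p][u] = members[p].get(u, 0.0) + w * scale
            w_new = w_total[p] + w_s_new
            rest = others[others != p]
            if rest.size:
                K[rest, p] = (w_total[p] * K[rest, p] + w_s_new * K[rest, s]) / w_new
                K[p, rest] += K[s, rest]
            w_total[p] = w_new
            mass[p] += mass[s]
            mass[s] = 0.0
            parent[s] = p
        K[s, :] = 0.0
        K[:, s] = 0.0
        active[s] = False
        act = np.flatnonzero(active)
        K[act, act] = 0.0
        K[act, act] = -K[np.ix_(act, act)].sum(axis=0)

    act = np.flatnonzero(active)
    surviving = [order[k] for k in act]
    red_gibbs = None
    if rm.node_gibbs is not None:
        rt = rt_kj(rm.temperature)
        red_gibbs = rm.node_gibbs.min() - rt * np.log(w_total[act])
    reduced = RateMatrix(K[np.ix_(act, act)], surviving, rm.temperature,
                         node_gibbs=red_gibbs)

    max_rate = float(rm.escape_rates().max(initial=0.0))
    times = time_grid(t_final, max_rate, points_per_decade)

    def reconstruct(p_mass: np.ndarray) -> np.ndarray:
        """Full-space populations from superstate masses (rows = times)."""
        out = np.zeros((p_mass.shape[0], n))
        for col, rep in enumerate(act):
            wm = members[rep]
            tot = w_total[rep]
            if tot <= 0:
                tot = sum(wm.values()) or 1.0
            for u, w in wm.items():
                out[:, u] = p_mass[:, col] * (w / tot)
        for s, norm, a, esc_s in reversed(schur_recon):
            p_s = out @ a / esc_s
            for u, w in norm.items():
                out[:, u] = p_s * w
        out = np.clip(out, 0.0, None)
        out /= out.sum(axis=1, keepdims=True)
        return out

    total = mass[act].sum()
    P_mass = _propagate_grid(reduced, mass[act] / total, times) * total
    # the endpoint goes through one well-conditioned matrix exponential of
    # the (de-stiffened) reduced generator rather than its eigenbasis
    if t_final > 0:
        P_mass[-1] = expm(reduced.dense() * t_final) @ mass[act]
    P = reconstruct(P_mass)

    trajectory = KineticTrajectory(times, P, order)
    esc0 = rm.escape_rates()
    idx = {nid: k for k, nid in enumerate(order)}
    for step in steps:
        i = idx[step.node]
        step.transit_population = float(np.trapezoid(esc0[i] * P[:, i], times))

    superstates: dict[str, list[str]] = {s: [] for s in surviving}
    alive = set(act.tolist())
    for i in parent:
        root = i
        while root not in alive:
            root = parent[root]
        superstates[order[root]].append(order[i])
    record = ContractionRecord(
        steps, superstates, surviving, float(rate_threshold), safety, trajectory,
        reduced,
    )
    final = KineticState(P[-1], float(times[-1]), order)
    return final, record


# ---------------------------------------------------------------------------
# traffic volume


@dataclass
class TrafficVolumes:
    """Per-node population throughput V_i = ∫ (influx_i + outflow_i) dt."""

    per_node: pd.Series

    def __post_init__(self) -> None:
        if (self.per_node < 0).any():
            raise ValueError("traffic volumes must be nonnegative")

    def __getitem__(self, node_id: str) -> float:
        return float(self.per_node[node_id])

    def group_totals(self, node_to_group: Mapping[str, str]) -> pd.Series:
        """Aggregate per-node volumes into per-group totals."""
        groups = pd.Series({n: node_to_group[n] for n in self.per_node.index})
        return self.per_node.groupby(groups).sum()

    def log10(self) -> pd.Series:
        with np.errstate(divide="ignore"):
            return np.log10(self.per_node)


def _trajectory_of(sol) -> KineticTrajectory:
    if isinstance(sol, KineticTrajectory):
        return sol
    if isinstance(sol, ContractionRecord):
        if sol.trajectory is None:
            raise ValueError("contraction record carries no trajectory")
        return sol.trajectory
    raise TypeError(f"expected trajectory or contraction record, got {type(sol)!r}")


def traffic_volume(rm: RateMatrix, sol) -> TrafficVolumes:
    """Accumulate V_i = ∫₀ᵀ [Σ_j k[i←j]p_j + Σ_j k[j←i]p_i] dt per node.

    ``sol`` is either an exact :class:`KineticTrajectory` or a
    :class:`ContractionRecord`; both integrate the same expression against
    the *original* rate matrix, so the two routes agree wherever the
    contraction is accurate.
    """
    traj = _trajectory_of(sol)
    if traj.node_order != list(rm.node_order):
        raise ValueError("trajectory node order does not match rate matrix")
    K_off = rm.dense()
    np.fill_diagonal(K_off, 0.0)
    esc = rm.escape_rates()
    influx = traj.populations @ K_off.T
    outflow = traj.populations * esc[None, :]
    v = np.trapezoid(influx + outflow, traj.times, axis=0)
    v = np.clip(v, 0.0, None)
    return TrafficVolumes(pd.Series(v, index=traj.node_order, name="traffic_volume"))


def integrated_edge_flux(
    network: ReactionPathNetwork, rm: RateMatrix, sol
) -> pd.DataFrame:
    """Time-integrated net and gross population flux through each path.

    Net flux is ∫(k_{a→b}·p_a − k_{b→a}·p_b)dt (positive a→b); gross flux is
    the integral of the sum.  Useful for quantifying how much product forms
    through each mechanistic channel.
    """
    traj = _trajectory_of(sol)
    idx = {nid: k for k, nid in enumerate(traj.node_order)}
    gibbs = {nid: network.nodes[nid].gibbs for nid in network.nodes}
    rows = []
    for e in network.edges:
        g_eff = max(e.ts_gibbs, gibbs[e.eq_a], gibbs[e.eq_b])
        k_ab = eyring_rate(gibbs[e.eq_a], g_eff, network.temperature)
        k_ba = eyring_rate(gibbs[e.eq_b], g_eff, network.temperature)
        pa = traj.populations[:, idx[e.eq_a]]
        pb = traj.populations[:, idx[e.eq_b]]
        net = float(np.trapezoid(k_ab * pa - k_ba * pb, traj.times))
        gross = float(np.trapezoid(k_ab * pa + k_ba * pb, traj.times))
        rows.append((e.id, e.eq_a, e.eq_b, net, gross))
    return pd.DataFrame(
        rows, columns=["id", "eq_a", "eq_b", "net_flux_ab", "gross_flux"]
    ).set_index("id")
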