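"""Deterministic force-driven 2-D graph layout.

Under-damped point dynamics with elastic (spring) attraction along edges and
inverse-square repulsion between all node pairs, integrated with
semi-implicit Euler until the maximum net (spring + repulsion) force drops
below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class LayoutParams:
    k_spring: float = 1.0
    rest_length: float = 1.0
    q_repulse: float = 0.2
    gamma_damp: float = 1.5
    dt: float = 0.05
    max_steps: int = 50_000
    tol_force: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_spring <= 0 or self.q_repulse < 0:
            raise ValueError("k_spring must be positive and q_repulse non-negative")
        if self.rest_length < 0:
            raise ValueError("rest_length must be non-negative")
        if self.dt <= 0 or self.gamma_damp <= 0:
            raise ValueError("dt and gamma_damp must be positive")
        if self.dt * self.gamma_damp >= 2:
            raise ValueError("dt * gamma_damp must be < 2 for stability")
        if self.tol_force <= 0:
            raise ValueError("tol_force must be positive")


def _net_forces(
    pos: np.ndarray,
    edge_index: np.ndarray,
    edge_weight: np.ndarray,
    params: LayoutParams,
    rng: np.random.Generator,
) -> np.ndarray:
    n = pos.shape[0]
    force = np.zeros_like(pos)

    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    coincident = (dist < 1e-12) & ~np.eye(n, dtype=bool)
    if coincident.any():
        # deterministic jitter to break exact overlaps
        angle = rng.uniform(0, 2 * np.pi, size=n)
        jit = 1e-6 * np.column_stack([np.cos(angle), np.sin(angle)])
        pos += jit
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    # electric repulsion q / d^2 along the separation direction
    inv = params.q_repulse / dist**3
    force += (diff * inv[:, :, None]).sum(axis=1)

    if edge_index.size:
        u, v = edge_index[:, 0], edge_index[:, 1]
        d_vec = pos[u] - pos[v]
        d_len = np.linalg.norm(d_vec, axis=1)
        d_len = np.where(d_len < 1e-12, 1e-12, d_len)
        mag = -params.k_spring * edge_weight * (d_len - params.rest_length)
        f_edge = d_vec * (mag / d_len)[:, None]
        np.add.at(force, u, f_edge)
        np.add.at(force, v, -f_edge)
    return force


def layout(graph: nx.Graph, params: LayoutParams | None = None) -> pd.DataFrame:
    """Equilibrium 2-D coordinates for every node of ``graph``.

    Initial positions are seeded uniformly on the unit disc; edge weights
    scale spring stiffness. Returns a frame (node, x, y) with the
    convergence flag and step count in ``attrs``. Same seed, params and
    graph give bit-identical coordinates.
    """
    if params is None:
        params = LayoutParams()
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    rng = np.random.default_rng(params.seed)
    radius = np.sqrt(rng.uniform(0, 1, size=n))
    angle = rng.uniform(0, 2 * np.pi, size=n)
    pos = np.column_stack([radius * np.cos(angle), radius * np.sin(angle)])
    vel = np.zeros_like(pos)

    index = {node: i for i, node in enumerate(nodes)}
    if graph.number_of_edges():
        edge_index = np.array([(index[u], index[v]) for u, v in graph.edges])
        edge_weight = np.array(
            [float(d.get("weight", 1.0)) for _, _, d in graph.edges(data=True)]
        )
    else:
        edge_index = np.empty((0, 2), dtype=int)
        edge_weight = np.empty(0)

    converged = False
    step = 0
    for step in range(1, params.max_steps + 1):
        force = _net_forces(pos, edge_index, edge_weight, params, rng)
        max_force = float(np.abs(np.linalg.norm(force, axis=1)).max()) if n > 1 else 0.0
        if max_force < params.tol_force:
            converged = True
            break
        # semi-implicit Euler with viscous damping
        vel = vel + params.dt * (force - params.gamma_damp * vel)
        pos = pos + params.dt * vel
        if not np.all(np.isfinite(pos)) or np.abs(pos).max() > 1e6:
            raise FloatingPointError(
                "layout diverged; reduce dt or increase gamma_damp"
            )
    out = pd.DataFrame({"node": nodes, "x": pos[:, 0], "y": pos[:, 1]})
    out.attrs["converged"] = converged
    out.attrs["steps"] = step
    out.attrs["max_force"] = float(
        np.abs(
            np.linalg.norm(
                _net_forces(pos, edge_index, edge_weight, params, rng), axis=1
            )
        ).max()
    ) if n > 1 else 0.0
    return out
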