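"""Vascular network container and serialization.

A :class:`VascularNetwork` is a graph of vessel segments between spatial
nodes.  Nodes carry a role (``inlet`` at the heart, ``internal``, ``pial``
for pial-surface junctions, ``outlet`` for penetrating-artery roots) and a
perfusion-territory label.  Vessels carry reference radius, length, wall
Young's modulus and a collateral flag; after discretization each element
also remembers its parent vessel and arc position, which is how a thrombus
is mapped onto a contiguous span of its host vessel.

Serialization is two CSV tables (``nodes.csv``, ``vessels.csv``) plus an
optional GraphML export via networkx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

ROLES = ("inlet", "internal", "pial", "outlet")

#: the eight brain perfusion territories plus the extracranial remainder
TERRITORIES = (
    "L-MCA", "R-MCA", "L-ACA", "R-ACA", "L-PCA", "R-PCA",
    "cerebellum", "brainstem", "systemic",
)
BRAIN_TERRITORIES = TERRITORIES[:-1]


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,), mm
    role: str
    territory: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown node role {self.role!r}")
        if self.territory not in TERRITORIES:
            raise ValueError(f"unknown territory {self.territory!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: non-finite position")


@dataclass
class VesselSpec:
    id: int
    node_a: int
    node_b: int
    r0_mm: float
    length_mm: float
    E_Pa: float
    is_collateral: bool = False
    territory: str = "systemic"
    # set by discretize()/apply_thrombus(); parent vessel id and arc offset of
    # this element's proximal end along the parent, in mm
    parent_id: int | None = None
    arc_pos_mm: float = 0.0
    thrombosed: bool = False

    def __post_init__(self) -> None:
        if self.r0_mm <= 0:
            raise ValueError(f"vessel {self.id}: r0_mm must be > 0")
        if self.length_mm <= 0:
            raise ValueError(f"vessel {self.id}: length_mm must be > 0")
        if self.E_Pa <= 0:
            raise ValueError(f"vessel {self.id}: E_Pa must be > 0")


@dataclass
class VascularNetwork:
    """Directed-by-convention graph of vessels; flow signs follow (node_a -> node_b)."""

    nodes: list[Node] = field(default_factory=list)
    vessels: list[VesselSpec] = field(default_factory=list)
    brain_volume_ml: float = 1390.0
    # generator metadata (territory root vessels, default thrombus host, ...)
    meta: dict = field(default_factory=dict)

    # ---- basic accessors -------------------------------------------------
    def node_by_id(self, nid: int) -> Node:
        return self._node_index()[nid]

    def _node_index(self) -> dict[int, Node]:
        return {n.id: n for n in self.nodes}

    def vessel_by_id(self, vid: int) -> VesselSpec:
        for v in self.vessels:
            if v.id == vid:
                return v
        raise KeyError(f"no vessel with id {vid}")

    @property
    def inlet_node(self) -> Node:
        inlets = [n for n in self.nodes if n.role == "inlet"]
        if len(inlets) != 1:
            raise ValueError(f"network must have exactly one inlet, found {len(inlets)}")
        return inlets[0]

    @property
    def outlet_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == "outlet"]

    @property
    def pial_outlet_nodes(self) -> list[Node]:
        """Penetrating-artery outlets on the pial surface (excludes systemic)."""
        return [n for n in self.outlet_nodes if n.territory != "systemic"]

    @property
    def n_total(self) -> int:
        """Total number of pial-surface outlets (N_total)."""
        return len(self.pial_outlet_nodes)

    @property
    def territory_outlet_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n in self.outlet_nodes:
            counts[n.territory] = counts.get(n.territory, 0) + 1
        return counts

    def next_node_id(self) -> int:
        return max((n.id for n in self.nodes), default=-1) + 1

    def next_vessel_id(self) -> int:
        return max((v.id for v in self.vessels), default=-1) + 1

    # ---- graph views -----------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, x=n.position[0], y=n.position[1], z=n.position[2],
                       role=n.role, territory=n.territory)
        for v in self.vessels:
            g.add_edge(v.node_a, v.node_b, id=v.id, r0_mm=v.r0_mm,
                       length_mm=v.length_mm, E_Pa=v.E_Pa,
                       is_collateral=v.is_collateral, territory=v.territory)
        return g

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on the first failure."""
        _ = self.inlet_node
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        g = self.to_networkx()
        if g.number_of_nodes() and not nx.is_connected(g):
            comps = list(nx.connected_components(g))
            raise ValueError(f"network is disconnected ({len(comps)} components)")
        for n in self.outlet_nodes:
            if g.degree(n.id) != 1:
                raise ValueError(f"outlet node {n.id} has degree {g.degree(n.id)} != 1")

    # ---- serialization ---------------------------------------------------
    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            {
                "id": [n.id for n in self.nodes],
                "x": [n.position[0] for n in self.nodes],
                "y": [n.position[1] for n in self.nodes],
                "z": [n.position[2] for n in self.nodes],
                "role": [n.role for n in self.nodes],
                "territory": [n.territory for n in self.nodes],
            }
        )
        vessels = pd.DataFrame(
            {
                "id": [v.id for v in self.vessels],
                "node_a": [v.node_a for v in self.vessels],
                "node_b": [v.node_b for v in self.vessels],
                "r0_mm": [v.r0_mm for v in self.vessels],
                "length_mm": [v.length_mm for v in self.vessels],
                "E_Pa": [v.E_Pa for v in self.vessels],
                "is_collateral": [v.is_collateral for v in self.vessels],
                "territory": [v.territory for v in self.vessels],
            }
        )
        return nodes, vessels

    def save_csv(self, directory: str | Path) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes, vessels = self.to_dataframes()
        nodes.to_csv(directory / "nodes.csv", index=False)
        vessels.to_csv(directory / "vessels.csv", index=False)
        if self.meta:
            with (directory / "meta.json").open("w") as fh:
                json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def from_dataframes(cls, nodes: pd.DataFrame, vessels: pd.DataFrame,
                        brain_volume_ml: float = 1390.0) -> "VascularNetwork":
        node_objs = [
            Node(int(r.id), np.array([r.x, r.y, r.z]), str(r.role), str(r.territory))
            for r in nodes.itertuples()
        ]
        vessel_objs = [
            VesselSpec(int(r.id), int(r.node_a), int(r.node_b), float(r.r0_mm),
                       float(r.length_mm), float(r.E_Pa), bool(r.is_collateral),
                       str(r.territory))
            for r in vessels.itertuples()
        ]
        return cls(node_objs, vessel_objs, brain_volume_ml)

    @classmethod
    def load_csv(cls, directory: str | Path,
                 brain_volume_ml: float = 1390.0) -> "VascularNetwork":
        import json

        directory = Path(directory)
        nodes = pd.read_csv(directory / "nodes.csv")
        vessels = pd.read_csv(directory / "vessels.csv")
        net = cls.from_dataframes(nodes, vessels, brain_volume_ml)
        meta_path = directory / "meta.json"
        if meta_path.exists():
            with meta_path.open() as fh:
                net.meta = json.load(fh)
        return net

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def discretize(network: VascularNetwork, max_dx_mm: float = 2.5,
               min_nodes: int = 3) -> VascularNetwork:
    """Split every vessel so each has >= ``min_nodes`` nodes and spacing <= ``max_dx_mm``.

    Total length and radii are preserved exactly; new elements carry
    ``parent_id`` and ``arc_pos_mm`` so thrombi can be mapped back onto the
    undiscretized host vessel.  Already-discretized networks are re-split
    from their parents' geometry unchanged.
    """
    if max_dx_mm <= 0:
        raise ValueError("max_dx_mm must be > 0")
    if min_nodes < 2:
        raise ValueError("min_nodes must be >= 2")
    new_nodes = [replace(n, position=n.position.copy()) for n in network.nodes]
    new_vessels: list[VesselSpec] = []
    next_nid = network.next_node_id()
    next_vid = 0
    node_pos = {n.id: n.position for n in network.nodes}
    for v in network.vessels:
        n_seg = max(min_nodes - 1, math.ceil(v.length_mm / max_dx_mm - 1e-12))
        pa, pb = node_pos[v.node_a], node_pos[v.node_b]
        prev = v.node_a
        parent = v.parent_id if v.parent_id is not None else v.id
        for k in range(n_seg):
            if k == n_seg - 1:
                nxt = v.node_b
            else:
                t = (k + 1) / n_seg
                new_nodes.append(Node(next_nid, pa + t * (pb - pa), "internal",
                                      v.territory))
                nxt = next_nid
                next_nid += 1
            new_vessels.append(VesselSpec(
                next_vid, prev, nxt, v.r0_mm, v.length_mm / n_seg, v.E_Pa,
                v.is_collateral, v.territory, parent_id=parent,
                arc_pos_mm=v.arc_pos_mm + k * v.length_mm / n_seg,
                thrombosed=v.thrombosed,
            ))
            next_vid += 1
            prev = nxt
    return VascularNetwork(new_nodes, new_vessels, network.brain_volume_ml,
                           dict(network.meta))
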