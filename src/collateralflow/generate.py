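"""Synthetic cerebral vasculature generator.

Builds a desk-scale stand-in for a patient vascular network:

* a small surrogate systemic tree (heart -> aorta -> carotids/vertebrals ->
  circle-of-Willis branches) with literature-typical dimensions;
* a pial vessel network as the dual graph of a geodesic-sphere
  triangulation (3-regular away from territory seams), all vessels at the
  pial reference radius;
* leptomeningeal collaterals: the territory-crossing pial edges, each
  retained independently with a configurable probability (the model's
  collateral score);
* Murray-law bifurcating trees feeding each territory, built by recursive
  spatial bisection of the territory's pial nodes so that every pial node
  is reached by exactly one tree leaf;
* one penetrating-artery stub per pial node, terminating in a model
  outlet.

Vessel lengths inside the trees follow the metabolic scaling
``length = length_radius_ratio * radius``; the pial mesh uses its actual
geometric edge lengths.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import NetworkConfig
from .network import Node, VascularNetwork, VesselSpec, discretize  # noqa: F401
from .surface import assign_territories, dual_mesh, icosphere

#: Young's modulus of all cerebral vessels, Pa
CEREBRAL_E_PA = 1.6e6
#: Young's modulus of the large systemic arteries (surrogate), Pa
SYSTEMIC_E_PA = 0.4e6

# ---------------------------------------------------------------------------
# Murray's law primitives
# ---------------------------------------------------------------------------


def murray_daughter_radii(parent_radius: float, split_fraction: float,
                          exponent: float = 3.0) -> tuple[float, float]:
    """Daughter radii at a bifurcation obeying Murray's law.

    The parent radius R and daughters r_i, r_j satisfy R**n = r_i**n + r_j**n
    with r_i**n = split_fraction * R**n.
    """
    if parent_radius <= 0:
        raise ValueError("parent_radius must be > 0")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    r_i = parent_radius * split_fraction ** (1.0 / exponent)
    r_j = parent_radius * (1.0 - split_fraction) ** (1.0 / exponent)
    return r_i, r_j


def build_bifurcating_tree(root_radius: float, terminal_radius: float,
                           config: NetworkConfig | None = None,
                           split_jitter: float = 0.0,
                           seed: int | None = None) -> VascularNetwork:
    """Symmetric Murray bifurcating tree from ``root_radius`` down to leaves.

    Bifurcation stops (inclusively) once a daughter radius falls to
    ``terminal_radius`` or below.  Segment length is
    ``length_radius_ratio * radius``.  With ``split_jitter`` > 0 the split
    fraction is drawn uniformly from 0.5 +/- jitter with a seeded RNG.

    The returned subnetwork's ``meta`` holds ``root`` (node id), ``leaves``
    (leaf node ids) and ``depth``.
    """
    config = config or NetworkConfig()
    if not root_radius > terminal_radius > 0:
        raise ValueError("need root_radius > terminal_radius > 0")
    if not 0.0 <= split_jitter < 0.5:
        raise ValueError("split_jitter must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    ratio, n_exp = config.length_radius_ratio, config.murray_exponent
    net = VascularNetwork(brain_volume_ml=config.brain_volume_ml)
    net.nodes.append(Node(0, np.zeros(3), "internal", "systemic"))
    leaves: list[int] = []
    max_depth = 0

    def grow(parent_node: int, radius: float, depth: int, x: float, span: float) -> None:
        nonlocal max_depth
        f = 0.5 if split_jitter == 0 else rng.uniform(0.5 - split_jitter, 0.5 + split_jitter)
        for side, r in enumerate(murray_daughter_radii(radius, f, n_exp)):
            nid = net.next_node_id()
            dx = x + (side - 0.5) * span  # schematic layout only
            net.nodes.append(Node(nid, np.array([dx, 0.0, -float(depth)]),
                                  "internal", "systemic"))
            net.vessels.append(VesselSpec(net.next_vessel_id(), parent_node, nid,
                                          r, ratio * r, CEREBRAL_E_PA))
            max_depth = max(max_depth, depth)
            # inclusive tie: a leaf exactly at the terminal radius terminates
            if r <= terminal_radius * (1 + 1e-12):
                leaves.append(nid)
            else:
                grow(nid, r, depth + 1, dx, span / 2)

    grow(0, root_radius, 1, 0.0, 1.0)
    net.meta = {"root": 0, "leaves": leaves, "depth": max_depth}
    return net


# ---------------------------------------------------------------------------
# Pial surface network
# ---------------------------------------------------------------------------


def sphere_radius_mm(brain_volume_ml: float) -> float:
    """Radius of the sphere with the configured brain volume."""
    return (3.0 * brain_volume_ml * 1e3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def build_pial_network(config: NetworkConfig) -> VascularNetwork:
    """Pial vessel network: dual graph of the triangulated synthetic surface.

    All territory-crossing edges are marked ``is_collateral`` and retained;
    apply :func:`select_collaterals` to thin them to a collateral score.
    ``meta['n_pial']`` records the pial node count (= future N_total).
    """
    if config.surface_resolution < 1:
        raise ValueError("surface_resolution must be >= 1")
    verts, faces = icosphere(config.surface_resolution)
    radius = sphere_radius_mm(config.brain_volume_ml)
    centroids, dual_edges = dual_mesh(verts, faces, radius=radius)
    territories = assign_territories(centroids)
    net = VascularNetwork(brain_volume_ml=config.brain_volume_ml)
    for i, (pos, terr) in enumerate(zip(centroids, territories)):
        net.nodes.append(Node(i, pos, "pial", str(terr)))
    for vid, (a, b) in enumerate(dual_edges):
        length = float(np.linalg.norm(centroids[a] - centroids[b]))
        crossing = territories[a] != territories[b]
        net.vessels.append(VesselSpec(vid, int(a), int(b), config.pial_radius_mm,
                                      length, CEREBRAL_E_PA,
                                      is_collateral=bool(crossing),
                                      territory=str(territories[a])))
    net.meta = {"n_pial": len(net.nodes)}
    return net


def select_collaterals(network: VascularNetwork, probability: float,
                       seed: int) -> VascularNetwork:
    """Retain each territory-crossing pial vessel independently with ``probability``.

    Non-crossing vessels are untouched.  Deterministic under a fixed seed.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    candidates = [v for v in network.vessels if v.is_collateral]
    keep = rng.random(len(candidates)) < probability
    drop = {v.id for v, k in zip(candidates, keep) if not k}
    vessels = [replace(v) for v in network.vessels if v.id not in drop]
    net = VascularNetwork([replace(n, position=n.position.copy()) for n in network.nodes],
                          vessels, network.brain_volume_ml, dict(network.meta))
    net.meta["n_collateral_candidates"] = len(candidates)
    net.meta["n_collateral_retained"] = int(keep.sum())
    return net


def attach_outlets(network: VascularNetwork,
                   config: NetworkConfig) -> VascularNetwork:
    """Attach one penetrating-artery stub (ending in an outlet) per pial node.

    The stub points radially inward with the cortical-thickness length and
    the pial reference radius.  ``meta`` gains ``n_total`` and
    ``territory_outlet_counts``.
    """
    net = VascularNetwork([replace(n, position=n.position.copy()) for n in network.nodes],
                          [replace(v) for v in network.vessels],
                          network.brain_volume_ml, dict(network.meta))
    nid = net.next_node_id()
    vid = net.next_vessel_id()
    for pn in [n for n in net.nodes if n.role == "pial"]:
        r = np.linalg.norm(pn.position)
        pos = pn.position * ((r - config.penetrating_length_mm) / r) if r > 0 else pn.position
        net.nodes.append(Node(nid, pos, "outlet", pn.territory))
        net.vessels.append(VesselSpec(vid, pn.id, nid, config.pial_radius_mm,
                                      config.penetrating_length_mm, CEREBRAL_E_PA,
                                      territory=pn.territory))
        nid += 1
        vid += 1
    net.meta["n_total"] = net.n_total
    net.meta["territory_outlet_counts"] = net.territory_outlet_counts
    return net


# ---------------------------------------------------------------------------
# Surrogate systemic tree (heart to circle of Willis)
# ---------------------------------------------------------------------------

#: SURROGATE large-artery table (the source publication references an
#: appendix table that is not available); literature-typical radii/lengths,
#: user-overridable.  Columns: name, from-node, to-node, radius mm,
#: length mm, E Pa, territory.
SYSTEMIC_SURROGATE_VESSELS: tuple[tuple[str, str, str, float, float, float, str], ...] = (
    ("ascending_aorta", "heart", "arch1", 12.0, 40.0, SYSTEMIC_E_PA, "systemic"),
    ("aortic_arch", "arch1", "arch2", 11.0, 40.0, SYSTEMIC_E_PA, "systemic"),
    ("descending_aorta", "arch2", "systemic_out", 10.0, 200.0, SYSTEMIC_E_PA, "systemic"),
    ("r_common_carotid", "arch1", "rcc", 3.5, 100.0, SYSTEMIC_E_PA, "systemic"),
    ("l_common_carotid", "arch2", "lcc", 3.5, 100.0, SYSTEMIC_E_PA, "systemic"),
    ("r_internal_carotid", "rcc", "rica", 2.5, 120.0, SYSTEMIC_E_PA, "systemic"),
    ("l_internal_carotid", "lcc", "lica", 2.5, 120.0, SYSTEMIC_E_PA, "systemic"),
    ("r_vertebral", "arch1", "vjunction", 1.9, 150.0, SYSTEMIC_E_PA, "systemic"),
    ("l_vertebral", "arch2", "vjunction", 1.9, 150.0, SYSTEMIC_E_PA, "systemic"),
    ("basilar", "vjunction", "basilar_end", 1.6, 25.0, CEREBRAL_E_PA, "systemic"),
    ("r_mca_m1", "rica", "root:R-MCA", 1.4, 30.0, CEREBRAL_E_PA, "R-MCA"),
    ("l_mca_m1", "lica", "root:L-MCA", 1.4, 30.0, CEREBRAL_E_PA, "L-MCA"),
    ("r_aca_a1", "rica", "root:R-ACA", 1.2, 25.0, CEREBRAL_E_PA, "R-ACA"),
    ("l_aca_a1", "lica", "root:L-ACA", 1.2, 25.0, CEREBRAL_E_PA, "L-ACA"),
    ("r_pca_p1", "basilar_end", "root:R-PCA", 1.1, 25.0, CEREBRAL_E_PA, "R-PCA"),
    ("l_pca_p1", "basilar_end", "root:L-PCA", 1.1, 25.0, CEREBRAL_E_PA, "L-PCA"),
    ("cerebellar", "basilar_end", "root:cerebellum", 1.3, 20.0, CEREBRAL_E_PA, "cerebellum"),
    ("brainstem_perforator", "basilar_end", "root:brainstem", 1.0, 15.0, CEREBRAL_E_PA,
     "brainstem"),
)

# schematic positions (mm) for the systemic junction nodes; cosmetic only --
# hydraulic lengths come from the table above
_SYSTEMIC_NODE_POS = {
    "heart": (0.0, 0.0, -320.0),
    "arch1": (5.0, 0.0, -280.0),
    "arch2": (-5.0, 0.0, -280.0),
    "systemic_out": (-5.0, 0.0, -480.0),
    "rcc": (25.0, 0.0, -190.0),
    "lcc": (-25.0, 0.0, -190.0),
    "rica": (25.0, 5.0, -110.0),
    "lica": (-25.0, 5.0, -110.0),
    "vjunction": (0.0, -20.0, -170.0),
    "basilar_end": (0.0, -25.0, -120.0),
}

# approximate outward directions of the territory roots on the sphere
_ROOT_DIRECTIONS = {
    "R-MCA": (1.0, 0.0, 0.15),
    "L-MCA": (-1.0, 0.0, 0.15),
    "R-ACA": (0.5, 0.85, 0.15),
    "L-ACA": (-0.5, 0.85, 0.15),
    "R-PCA": (0.5, -0.85, 0.15),
    "L-PCA": (-0.5, -0.85, 0.15),
    "cerebellum": (0.0, -0.3, -0.95),
    "brainstem": (0.0, 0.0, -1.0),
}


def build_systemic_tree(config: NetworkConfig,
                        table=SYSTEMIC_SURROGATE_VESSELS) -> VascularNetwork:
    """Surrogate systemic tree from the heart to the territory root nodes.

    ``meta['territory_roots']`` maps territory -> root node id and
    ``meta['territory_root_vessels']`` maps territory -> feeding vessel id
    (the right-MCA entry is the default thrombus host, the M1).
    """
    net = VascularNetwork(brain_volume_ml=config.brain_volume_ml)
    r_sphere = sphere_radius_mm(config.brain_volume_ml)
    name_to_id: dict[str, int] = {}
    territory_roots: dict[str, int] = {}
    root_vessels: dict[str, int] = {}

    def node_id(name: str, territory: str) -> int:
        if name in name_to_id:
            return name_to_id[name]
        nid = net.next_node_id()
        if name == "heart":
            pos, role = _SYSTEMIC_NODE_POS[name], "inlet"
        elif name == "systemic_out":
            pos, role = _SYSTEMIC_NODE_POS[name], "outlet"
        elif name.startswith("root:"):
            terr = name.split(":", 1)[1]
            d = np.asarray(_ROOT_DIRECTIONS[terr])
            pos = 0.8 * r_sphere * d / np.linalg.norm(d)
            role = "internal"
            territory_roots[terr] = nid
        else:
            pos, role = _SYSTEMIC_NODE_POS[name], "internal"
        net.nodes.append(Node(nid, np.asarray(pos, dtype=float), role, territory))
        name_to_id[name] = nid
        return nid

    for name, a, b, r_mm, length_mm, e_pa, territory in table:
        na = node_id(a, "systemic")
        nb = node_id(b, territory if b.startswith("root:") else "systemic")
        vid = net.next_vessel_id()
        net.vessels.append(VesselSpec(vid, na, nb, r_mm, length_mm, e_pa,
                                      territory=territory))
        if b.startswith("root:"):
            root_vessels[b.split(":", 1)[1]] = vid
    net.meta = {
        "territory_roots": territory_roots,
        "territory_root_vessels": root_vessels,
        "systemic_outlet": name_to_id["systemic_out"],
    }
    return net


# ---------------------------------------------------------------------------
# Territory feeding trees and full assembly
# ---------------------------------------------------------------------------


def _grow_feeding_tree(net: VascularNetwork, parent_node: int, radius: float,
                       pial_ids: list[int], positions: dict[int, np.ndarray],
                       config: NetworkConfig, territory: str) -> None:
    """Murray tree by recursive spatial bisection of a territory's pial nodes.

    Every subset split uses the subset-size fraction as the Murray split
    fraction, so each leaf radius is root_radius * (1/n)**(1/exponent) for
    symmetric counts and leaf cubes always sum to the root cube.  The leaf
    vessel attaches directly to its pial node.
    """
    if len(pial_ids) == 1:
        pid = pial_ids[0]
        net.vessels.append(VesselSpec(net.next_vessel_id(), parent_node, pid,
                                      radius, config.length_radius_ratio * radius,
                                      CEREBRAL_E_PA, territory=territory))
        return
    pts = np.array([positions[i] for i in pial_ids])
    axis = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
    order = np.argsort(pts[:, axis], kind="stable")
    half = len(pial_ids) // 2
    groups = ([pial_ids[i] for i in order[:half]], [pial_ids[i] for i in order[half:]])
    f = half / len(pial_ids)
    radii = murray_daughter_radii(radius, f, config.murray_exponent)
    for r, group in zip(radii, groups):
        centroid = np.mean([positions[i] for i in group], axis=0)
        nid = net.next_node_id()
        net.nodes.append(Node(nid, centroid, "internal", territory))
        net.vessels.append(VesselSpec(net.next_vessel_id(), parent_node, nid, r,
                                      config.length_radius_ratio * r,
                                      CEREBRAL_E_PA, territory=territory))
        _grow_feeding_tree(net, nid, r, group, positions, config, territory)


def resolution_for_outlets(n_outlet_target: int) -> int:
    """Smallest icosphere refinement whose face count reaches the target."""
    k = 1
    while 20 * 4 ** k < n_outlet_target:
        k += 1
    return k


def generate_network(config: NetworkConfig) -> VascularNetwork:
    """Generate the full synthetic vasculature (undiscretized).

    Assembly: surrogate systemic tree, pial dual-mesh network with
    collaterals thinned to ``collateral_probability``, one Murray feeding
    tree per territory, one penetrating-artery outlet per pial node.
    Deterministic for a fixed ``config.seed``.
    """
    errs = config.validate()
    if errs:
        raise ValueError("; ".join(errs))
    cfg = config
    if config.n_outlet_target is not None:
        cfg = replace(config,
                      surface_resolution=resolution_for_outlets(config.n_outlet_target))
    collateral_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)

    systemic = build_systemic_tree(cfg)
    pial = build_pial_network(cfg)
    pial = select_collaterals(pial, cfg.collateral_probability, collateral_seed)

    # merge: offset pial ids above the systemic ones
    net = VascularNetwork(list(systemic.nodes), list(systemic.vessels),
                          cfg.brain_volume_ml, dict(systemic.meta))
    node_off = net.next_node_id()
    vessel_off = net.next_vessel_id()
    for n in pial.nodes:
        net.nodes.append(replace(n, id=n.id + node_off, position=n.position.copy()))
    for v in pial.vessels:
        net.vessels.append(replace(v, id=v.id + vessel_off,
                                   node_a=v.node_a + node_off,
                                   node_b=v.node_b + node_off))
    net.meta.update({k: pial.meta[k] for k in
                     ("n_collateral_candidates", "n_collateral_retained")})

    positions = {n.id: n.position for n in net.nodes}
    pial_by_territory: dict[str, list[int]] = {}
    for n in net.nodes:
        if n.role == "pial":
            pial_by_territory.setdefault(n.territory, []).append(n.id)
    roots = net.meta["territory_roots"]
    root_radius = {terr: net.vessel_by_id(vid).r0_mm
                   for terr, vid in net.meta["territory_root_vessels"].items()}
    for terr, ids in sorted(pial_by_territory.items()):
        _grow_feeding_tree(net, roots[terr], root_radius[terr], sorted(ids),
                           positions, cfg, terr)

    net = attach_outlets(net, cfg)
    net.meta["thrombus_vessel"] = net.meta["territory_root_vessels"]["R-MCA"]
    net.meta["seed"] = cfg.seed
    net.meta["collateral_probability"] = cfg.collateral_probability
    net.validate()
    return net
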