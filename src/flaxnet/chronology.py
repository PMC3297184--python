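"""Calibration-based substitution-rate estimation and node dating on the
haplotype network.

A single calibration — a node assigned a known age T (years before
present) and a substitution depth k over L sites — fixes the clock rate

    r = k / (L · T)   [substitutions / site / year]

Every other node is then dated by its substitution depth d to its
sampled descendant tips: age = d / (r · L).  Because the network is
unrooted, "descendant" is defined relative to a root node (by default
the domestication common ancestor): a sampled node t is a descendant of
v when v lies on a shortest parsimony path from the root to t.  Depths
over multiple tips are combined according to ``depth_mode``
(mean_tip_path, the default, or min/max_tip_path); on reticulations the
minimum-substitution route is used and flagged in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .alignment import InputError
from .network import HaploNetwork

logger = logging.getLogger(__name__)

DEPTH_MODES = ("mean_tip_path", "max_tip_path", "min_tip_path")


@dataclass
class Calibration:
    """A node with a known age used to calibrate the clock."""

    node_id: str
    age_years: float
    k: float  # substitutions on the calibrated path
    L: int  # sites

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise InputError("calibration age must be > 0")
        if self.k < 1:
            raise InputError("uninformative calibration: k must be >= 1")
        if self.L < 1:
            raise InputError("L must be >= 1")


def calibrate_rate(cal: Calibration) -> float:
    """Clock rate r = k / (L · T) in substitutions/site/year."""
    return cal.k / (cal.L * cal.age_years)


@dataclass
class Chronology:
    rate: float  # substitutions / site / year
    L: int
    depth_mode: str
    depths: dict[str, float]  # node -> substitution depth d
    ages: dict[str, float]  # node -> years before present

    def age_of(self, node: str) -> float:
        return self.ages[node]


def node_depths(
    net: HaploNetwork, depth_mode: str = "mean_tip_path", root: str | None = None
) -> dict[str, float]:
    """Substitution depth of every node to its sampled descendant tips.

    The root orients the (otherwise unrooted) network; sampled nodes
    with no strict descendants get depth 0.
    """
    if depth_mode not in DEPTH_MODES:
        raise InputError(f"depth_mode must be one of {DEPTH_MODES}")
    g = net.graph
    if not nx.is_connected(g):
        raise InputError("network is disconnected")
    if root is None:
        root = net.dca_node if net.dca_node is not None else min(g.nodes)
    if any(g.degree(n) > 1 for n in g.nodes) and not nx.is_tree(g):
        logger.info("network has reticulations; depths use shortest routes")

    dist_root = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    sampled = [n for n in net.sampled_nodes()]
    dist_from: dict[str, dict[str, float]] = {
        n: nx.single_source_dijkstra_path_length(g, n, weight="weight")
        for n in g.nodes
    }
    depths: dict[str, float] = {}
    for v in sorted(g.nodes):
        tip_dists = []
        for t in sampled:
            if t == v:
                continue  # strict descendants: an extant ancestral
                # haplotype is dated by the lineages it founded
            on_path = abs(
                dist_root[v] + dist_from[v][t] - dist_root[t]
            ) < 1e-9
            if on_path:
                tip_dists.append(dist_from[v][t])
        if not tip_dists:
            tip_dists = [0.0]
        if depth_mode == "mean_tip_path":
            depths[v] = sum(tip_dists) / len(tip_dists)
        elif depth_mode == "max_tip_path":
            depths[v] = max(tip_dists)
        else:
            depths[v] = min(tip_dists)
    return depths


def date_nodes(
    net: HaploNetwork,
    rate: float,
    L: int,
    depth_mode: str = "mean_tip_path",
    root: str | None = None,
) -> Chronology:
    """Date every network node: age = depth / (rate · L)."""
    if rate <= 0:
        raise InputError("rate must be > 0")
    depths = node_depths(net, depth_mode, root)
    ages = {n: d / (rate * L) for n, d in depths.items()}
    return Chronology(rate=rate, L=L, depth_mode=depth_mode, depths=depths, ages=ages)


def calibrate_and_date(
    net: HaploNetwork,
    calibration_node: str,
    age_years: float,
    L: int,
    depth_mode: str = "mean_tip_path",
    root: str | None = None,
) -> tuple[Chronology, Calibration]:
    """Calibrate the rate from one network node of known age, then date
    all nodes.  The calibration node's depth under ``depth_mode`` plays
    the role of k, which makes its dated age reproduce T exactly."""
    depths = node_depths(net, depth_mode, root)
    if calibration_node not in depths:
        raise InputError(f"unknown calibration node: {calibration_node!r}")
    k = depths[calibration_node]
    if k <= 0:
        raise InputError(
            f"calibration node {calibration_node!r} has zero depth; "
            "pick an internal node"
        )
    cal = Calibration(node_id=calibration_node, age_years=age_years, k=k, L=L)
    rate = calibrate_rate(cal)
    ages = {n: d / (rate * L) for n, d in depths.items()}
    return (
        Chronology(rate=rate, L=L, depth_mode=depth_mode, depths=depths, ages=ages),
        cal,
    )


def export_chronology(chron: Chronology, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "node": sorted(chron.ages),
            "depth": [chron.depths[n] for n in sorted(chron.ages)],
            "age_years": [chron.ages[n] for n in sorted(chron.ages)],
            "depth_mode": chron.depth_mode,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_chronology(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
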