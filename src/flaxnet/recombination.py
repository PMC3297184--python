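"""Homoplasy probability model and binomial significance tests for
recombination.

Under a uniform mutation model a new mutation recurs at an
already-mutated alignment position *and* to the same derived base with
probability (1/3)·(1/L) per prior mutation, so with m substitutions on
the network the per-mutation homoplasy probability is

    p = (1/3) · (1/L) · m

and the expected number of homoplasies among the m network mutations is
E = m·p = m²/(3L).  A reticulation whose branch carries far more
homoplasies than this model predicts is better explained by
recombination than by repeat mutation; each candidate branch with N
substitutions of which H are homoplasious is scored with the upper-tail
binomial probability P(X >= H | N, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sps

from .alignment import InputError
from .network import HaploNetwork, count_homoplasies


@dataclass
class HomoplasyModel:
    """Per-mutation homoplasy probability for an alignment of L sites
    carrying m network substitutions."""

    L: int
    m: int
    p: float = field(init=False)
    E: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise InputError("alignment length must be >= 1")
        if self.m < 0:
            raise InputError("substitution count must be >= 0")
        self.p = self.m / (3.0 * self.L)
        self.E = self.m * self.p

    @property
    def p_printed(self) -> float:
        """p rounded to one significant figure (report-style mirror)."""
        return _round_sig(self.p, 1)

    @property
    def E_printed(self) -> float:
        """E truncated to two decimal places (report-style mirror)."""
        return np.trunc(self.E * 100) / 100


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def homoplasy_model(L: int, m: int) -> HomoplasyModel:
    """Build the homoplasy probability model: p = m/(3L), E = m²/(3L)."""
    return HomoplasyModel(L=L, m=m)


def branch_test(N: int, H: int, p: float) -> float:
    """Upper-tail binomial probability of observing H or more homoplasies
    among N branch substitutions, each homoplasious with probability p."""
    if not (0 <= H <= N):
        raise InputError(f"need 0 <= H <= N, got H={H}, N={N}")
    if not (0 < p < 1):
        raise InputError(f"need 0 < p < 1, got p={p}")
    if H == 0:
        return 1.0
    return float(sps.binom.sf(H - 1, N, p))


def network_test(model: HomoplasyModel, H_net: int) -> tuple[float, float]:
    """Network-wide homoplasy probabilities under Binomial(m, p).

    Returns ``(point, tail)``: the point probability P(X = H_net) and
    the upper tail P(X >= H_net).  Both are reported because published
    network summaries sometimes print the point value while defining an
    upper-tail test.
    """
    if H_net > model.m:
        raise InputError("H_net cannot exceed m")
    if model.m == 0 or model.p <= 0:
        return (1.0 if H_net == 0 else 0.0), (1.0 if H_net == 0 else 0.0)
    point = float(sps.binom.pmf(H_net, model.m, model.p))
    tail = 1.0 if H_net == 0 else float(sps.binom.sf(H_net - 1, model.m, model.p))
    return point, tail


@dataclass
class RecombEvent:
    """One reticulation tested for recombination."""

    event_id: str  # "R1"...
    cycle: list[str]  # node ids of the reticulation cycle
    tested_branch: tuple[str, str]
    N: int
    N_positions: list[str]
    H: int
    H_positions: list[str]
    ratio: float  # H / N as conventionally printed
    P_binom: float
    ancestral_candidates: tuple[str, str]
    ambiguous_branch: bool  # True when several cycle branches carried homoplasies
    significant_05: bool = field(init=False)
    significant_01: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant_05 = self.P_binom < 0.05
        self.significant_01 = self.P_binom < 0.01


def _cycle_edges(cycle: list[str], graph: nx.Graph) -> list[tuple[str, str]]:
    """Edges of the cycle in traversal order (cycle given as an ordered
    node list from networkx cycle_basis)."""
    return [
        tuple(sorted((cycle[i], cycle[(i + 1) % len(cycle)])))
        for i in range(len(cycle))
    ]


def enumerate_events(
    net: HaploNetwork, model: HomoplasyModel
) -> list[RecombEvent]:
    """One :class:`RecombEvent` per independent reticulation cycle.

    For each cycle in the network's cycle basis, the branch (edge) whose
    label carries homoplasious characters is tested with
    :func:`branch_test`; when several cycle branches carry homoplasies,
    all are tested and the event keeps the smallest P with an ambiguity
    flag.  The two ancestral candidates are the cycle neighbours of the
    recombinant node (the corners opposite one another across the
    reticulation).  Events are labelled R1..Rk ordered by distance from
    the DCA node (when identified), then by node ids.
    """
    graph = net.graph
    root = net.dca_node if net.dca_node is not None else min(graph.nodes)
    _, per_char = count_homoplasies(net)
    homoplasy_names = set(per_char)

    raw_cycles = nx.cycle_basis(graph, root=root)
    dist = nx.single_source_dijkstra_path_length(graph, root, weight="weight")
    cycles = sorted(
        (list(c) for c in raw_cycles),
        key=lambda c: (min(dist[n] for n in c), sorted(c)),
    )

    events: list[RecombEvent] = []
    for k, cycle in enumerate(cycles, start=1):
        edges = _cycle_edges(cycle, graph)
        candidates = []
        for u, v in edges:
            chars = graph.edges[u, v]["chars"]
            subs = [c for c in chars if c.kind == "substitution"]
            homo = [c for c in subs if c.name in homoplasy_names]
            if homo:
                N = len(subs)
                H = len(homo)
                P = branch_test(N, H, model.p)
                candidates.append(((u, v), N, subs, H, homo, P))
        if not candidates:
            continue  # a cycle driven purely by the indel character
        candidates.sort(key=lambda t: (t[5], t[0]))
        (u, v), N, subs, H, homo, P = candidates[0]
        # recombinant corner: tested-branch endpoint farther from the root
        recomb = v if dist[v] >= dist[u] else u
        idx = cycle.index(recomb)
        neighbours = tuple(
            sorted((cycle[idx - 1], cycle[(idx + 1) % len(cycle)]))
        )
        events.append(
            RecombEvent(
                event_id=f"R{k}",
                cycle=sorted(cycle),
                tested_branch=(u, v),
                N=N,
                N_positions=[c.name for c in subs],
                H=H,
                H_positions=[c.name for c in homo],
                ratio=H / N,
                P_binom=P,
                ancestral_candidates=neighbours,
                ambiguous_branch=len(candidates) > 1,
            )
        )
    return events


def events_table(events: list[RecombEvent]):
    """Events as a DataFrame mirroring the conventional report layout."""
    import pandas as pd

    rows = []
    for ev in events:
        rows.append(
            {
                "event": ev.event_id,
                "N": ev.N,
                "N_positions": ",".join(ev.N_positions),
                "H": ev.H,
                "H_positions": ",".join(ev.H_positions),
                "ratio": round(ev.ratio, 2),
                "P_binom": ev.P_binom,
                "ancestral_candidates": ",".join(ev.ancestral_candidates),
                "significant_05": ev.significant_05,
                "significant_01": ev.significant_01,
                "ambiguous_branch": ev.ambiguous_branch,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event", "N", "N_positions", "H", "H_positions", "ratio",
            "P_binom", "ancestral_candidates", "significant_05",
            "significant_01", "ambiguous_branch",
        ],
    )
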