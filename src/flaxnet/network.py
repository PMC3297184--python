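"""Haplotype collapsing and reticulate parsimony network construction.

Samples are collapsed into haplotypes over the segregating substitution
sites plus (optionally) indel presence/absence characters.  The network
is a median-joining-style parsimony graph built with epsilon = 0 on a
binary-recoded character matrix: every link belonging to some minimum
spanning tree is retained, so character conflict appears as cycles
(reticulations), and unsampled median vectors are inserted only where
they shorten the graph.

A *homoplasy* is a character that labels more than one edge of the
network — the same mutation arising independently on separate branches.
The total homoplasy count is the sum over characters of
(edge occurrences − 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .alignment import Alignment, InputError
from .popgen import BASES, SiteTable

logger = logging.getLogger(__name__)

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


def roman(k: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while k >= val:
            out.append(sym)
            k -= val
    return "".join(out)


# ---------------------------------------------------------------------------
# character matrix


@dataclass(frozen=True)
class Character:
    """One binary network character.

    Substitution characters are named ``"<position>"`` for biallelic
    sites and ``"<position>:<allele>"`` for the extra characters of a
    multi-allelic site (one per derived allele).  Indel characters are
    named ``"indel:<start>-<end>"``.
    """

    name: str
    position: int | None  # alignment column for substitutions, None for indels
    kind: str  # "substitution" | "indel"
    weight: float = 1.0


@dataclass
class CharacterMatrix:
    characters: list[Character]
    matrix: np.ndarray  # (n_samples, n_characters) of 0/1
    sample_ids: list[str]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.characters])


def character_matrix(
    aln: Alignment,
    table: SiteTable,
    indel_mode: str = "include",
    indel_weight: float = 1.0,
) -> CharacterMatrix:
    """Binary recoding of segregating sites (+ indel events).

    Each biallelic site becomes one 0/1 character (0 = majority allele);
    a site with k alleles becomes k−1 characters, one per non-majority
    allele.  Missing states are imputed to the majority allele with a
    logged warning.  With ``indel_mode="include"`` every indel event
    adds one presence/absence character of weight ``indel_weight``.
    """
    if indel_mode not in ("include", "exclude"):
        raise InputError(f"indel_mode must be include|exclude, got {indel_mode!r}")
    chars: list[Character] = []
    cols: list[np.ndarray] = []
    for pos in table.positions:
        states = table.states[pos]
        alleles = table.alleles[pos]
        missing = ~np.isin(states, list(BASES))
        if missing.any():
            logger.warning(
                "position %d: %d missing state(s) imputed to majority allele",
                pos, int(missing.sum()),
            )
        if len(alleles) == 2:
            chars.append(Character(str(pos), pos, "substitution"))
            cols.append((states == alleles[1]).astype(np.int8))
        else:
            for allele in alleles[1:]:
                chars.append(Character(f"{pos}:{allele}", pos, "substitution"))
                cols.append((states == allele).astype(np.int8))
    if indel_mode == "include":
        for ev in table.indel_events:
            chars.append(Character(ev.name, None, "indel", weight=indel_weight))
            cols.append(np.array(ev.presence, dtype=np.int8))
    matrix = (
        np.column_stack(cols) if cols else np.zeros((aln.n, 0), dtype=np.int8)
    )
    return CharacterMatrix(chars, matrix, list(aln.sample_ids))


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class Haplotype:
    haplotype_id: str  # stable internal id, "H01"...
    label: str  # Roman numeral in discovery order, "I"...
    states: tuple[int, ...]  # over CharacterMatrix.characters
    members: list[str]
    group_counts: dict[str, int]


def collapse_haplotypes(
    aln: Alignment,
    table: SiteTable,
    indel_mode: str = "include",
    indel_weight: float = 1.0,
) -> tuple[list[Haplotype], CharacterMatrix]:
    """Collapse samples with identical character-state vectors.

    Haplotype ids are assigned in order of each haplotype's first
    occurring member sample, which makes the collapse deterministic for
    a given input alignment.
    """
    cm = character_matrix(aln, table, indel_mode, indel_weight)
    by_states: dict[tuple[int, ...], Haplotype] = {}
    for i, sid in enumerate(cm.sample_ids):
        key = tuple(int(x) for x in cm.matrix[i])
        if key not in by_states:
            k = len(by_states) + 1
            by_states[key] = Haplotype(
                haplotype_id=f"H{k:02d}",
                label=roman(k),
                states=key,
                members=[],
                group_counts={},
            )
        hap = by_states[key]
        hap.members.append(sid)
        g = aln.groups[sid]
        hap.group_counts[g] = hap.group_counts.get(g, 0) + 1
    return list(by_states.values()), cm


# ---------------------------------------------------------------------------
# median-joining network


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
            return True
        return False


def _wdist(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w[u != v]))


def _msn_edges(
    vectors: dict[str, np.ndarray], weights: np.ndarray
) -> list[tuple[str, str, float]]:
    """Union of all minimum spanning trees (epsilon = 0 spanning network).

    An edge of weight w is retained iff its endpoints lie in different
    connected components of the graph restricted to strictly lighter
    edges — the standard criterion for membership in at least one MST.
    """
    ids = sorted(vectors)
    dists = []
    for u, v in itertools.combinations(ids, 2):
        dists.append((round(_wdist(vectors[u], vectors[v], weights), 9), u, v))
    dists.sort()
    dsu = _DSU(ids)
    edges: list[tuple[str, str, float]] = []
    for _, grp in itertools.groupby(dists, key=lambda t: t[0]):
        batch = list(grp)
        kept = [
            (u, v, d) for d, u, v in batch if dsu.find(u) != dsu.find(v)
        ]
        edges.extend(kept)
        for u, v, _ in kept:
            dsu.union(u, v)
    return edges


@dataclass
class HaploNetwork:
    graph: nx.Graph  # nodes: haplotype/median ids; edges carry "chars"
    haplotypes: dict[str, Haplotype]
    characters: list[Character]
    dca_node: str | None = None
    dca_scores: dict[str, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        """Total substitution-character occurrences over all edge labels,
        counting repeats (homoplasies) multiply."""
        count = 0
        for _, _, data in self.graph.edges(data=True):
            count += sum(1 for c in data["chars"] if c.kind == "substitution")
        return count

    def sampled_nodes(self) -> list[str]:
        return sorted(self.haplotypes)

    def median_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if n not in self.haplotypes)

    def char_edge_map(self) -> dict[str, list[tuple[str, str]]]:
        """character name -> edges whose label carries it (sorted)."""
        out: dict[str, list[tuple[str, str]]] = {}
        for u, v, data in sorted(self.graph.edges(data=True)):
            e = tuple(sorted((u, v)))
            for c in data["chars"]:
                out.setdefault(c.name, []).append(e)
        return out

    def reticulation_cycles(self) -> list[list[str]]:
        cycles = nx.cycle_basis(self.graph, root=min(self.graph.nodes))
        return sorted((sorted(c) for c in cycles), key=lambda c: (len(c), c))


def _median(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    return ((u.astype(int) + v.astype(int) + w.astype(int)) >= 2).astype(np.int8)


def build_network(
    haplotypes: list[Haplotype],
    characters: list[Character],
    max_rounds: int = 50,
) -> HaploNetwork:
    """Median-joining parsimony network over the haplotype character
    vectors (epsilon = 0).

    All minimum-length links are retained so that character conflict
    shows up as reticulation cycles.  Median (unsampled) vectors are
    added for connected node triples whenever the star through the
    median is strictly shorter than the existing two-link path, and
    pruned again when they end up with degree <= 2 (such medians lie on
    a path and do not shorten the graph).  Edge labels list the
    characters changing along each edge.
    """
    if not haplotypes:
        raise InputError("need at least one haplotype")
    weights = np.array([c.weight for c in characters])
    vectors: dict[str, np.ndarray] = {
        h.haplotype_id: np.array(h.states, dtype=np.int8) for h in haplotypes
    }
    seen_states = {tuple(v) for v in vectors.values()}
    n_median = 0

    if len(vectors) > 1:
        for _ in range(max_rounds):
            edges = _msn_edges(vectors, weights)
            adj: dict[str, list[str]] = {}
            for u, v, _ in edges:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            added = False
            for center in sorted(adj):
                for a, b in itertools.combinations(sorted(adj[center]), 2):
                    med = _median(vectors[a], vectors[center], vectors[b])
                    key = tuple(int(x) for x in med)
                    if key in seen_states:
                        continue
                    star = (
                        _wdist(vectors[a], med, weights)
                        + _wdist(vectors[center], med, weights)
                        + _wdist(vectors[b], med, weights)
                    )
                    path = _wdist(vectors[a], vectors[center], weights) + _wdist(
                        vectors[center], vectors[b], weights
                    )
                    if star < path:
                        n_median += 1
                        vectors[f"M{n_median:02d}"] = med
                        seen_states.add(key)
                        added = True
            if not added:
                break

        # prune median vectors that settle on a path (degree <= 2)
        hap_ids = {h.haplotype_id for h in haplotypes}
        while True:
            edges = _msn_edges(vectors, weights)
            degree: dict[str, int] = {k: 0 for k in vectors}
            for u, v, _ in edges:
                degree[u] += 1
                degree[v] += 1
            prunable = sorted(
                k for k in vectors if k not in hap_ids and degree[k] <= 2
            )
            if not prunable:
                break
            del vectors[prunable[0]]
        edges = _msn_edges(vectors, weights)
    else:
        edges = []

    g = nx.Graph()
    for node in sorted(vectors):
        g.add_node(node, states=tuple(int(x) for x in vectors[node]))
    for u, v, d in sorted(edges):
        diff = vectors[u] != vectors[v]
        chars = [characters[i] for i in np.flatnonzero(diff)]
        g.add_edge(u, v, chars=chars, weight=d)
    net = HaploNetwork(
        graph=g,
        haplotypes={h.haplotype_id: h for h in haplotypes},
        characters=list(characters),
    )
    assert nx.is_connected(g)
    return net


def count_homoplasies(net: HaploNetwork) -> tuple[int, dict[str, list[tuple[str, str]]]]:
    """Network homoplasy count and the per-character edge map.

    Only substitution characters are counted (the indel character is
    carried on the network but priced separately); each character
    contributes (number of edges bearing it − 1).
    """
    per_char = {
        name: edges
        for name, edges in net.char_edge_map().items()
        if not name.startswith("indel:") and len(edges) >= 2
    }
    h_net = sum(len(edges) - 1 for edges in per_char.values())
    return h_net, per_char


def identify_dca(
    net: HaploNetwork, cultivated_groups: list[str]
) -> tuple[str, dict[str, float]]:
    """Locate the domestication common ancestor (DCA) node.

    Scores every node by its total shortest parsimony path length to all
    nodes containing members of the cultivated groups; the minimum wins.
    Ties are broken by the number of homoplasious characters on the
    connecting paths, then by node id.  Returns the winning node and the
    full score table.
    """
    cultivated_nodes = sorted(
        hid
        for hid, hap in net.haplotypes.items()
        if any(g in cultivated_groups for g in hap.group_counts)
    )
    if not cultivated_nodes:
        raise InputError(f"no samples in cultivated groups {cultivated_groups}")
    _, per_char = count_homoplasies(net)
    homoplasy_names = set(per_char)
    scores: dict[str, float] = {}
    tiebreak: dict[str, int] = {}
    for node in sorted(net.graph.nodes):
        lengths = nx.single_source_dijkstra_path_length(
            net.graph, node, weight="weight"
        )
        scores[node] = sum(lengths[c] for c in cultivated_nodes)
        n_homo = 0
        for c in cultivated_nodes:
            path = nx.dijkstra_path(net.graph, node, c, weight="weight")
            for u, v in zip(path, path[1:]):
                n_homo += sum(
                    1
                    for ch in net.graph.edges[u, v]["chars"]
                    if ch.name in homoplasy_names
                )
        tiebreak[node] = n_homo
    winner = min(sorted(scores), key=lambda k: (scores[k], tiebreak[k], k))
    net.dca_node = winner
    net.dca_scores = scores
    return winner, scores


# ---------------------------------------------------------------------------
# exports


def export_haplotype_table(
    haplotypes: list[Haplotype],
    table: SiteTable,
    aln: Alignment,
    path: str | Path,
) -> None:
    """Per-sample table: sample, group, haplotype label, then one column
    per substitution position giving the base carried."""
    import pandas as pd

    rows = []
    for hap in haplotypes:
        for sid in hap.members:
            row = {"sample": sid, "group": aln.groups[sid], "haplotype": hap.label}
            seq = aln.row(sid)
            for pos in table.positions:
                row[str(pos)] = seq[pos - 1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_graphml(net: HaploNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        hap = net.haplotypes.get(node)
        g.add_node(
            node,
            kind="haplotype" if hap else "median",
            label=hap.label if hap else node,
            n_members=len(hap.members) if hap else 0,
            members=",".join(hap.members) if hap else "",
            is_dca=(node == net.dca_node),
        )
    for u, v, data in net.graph.edges(data=True):
        g.add_edge(
            u, v,
            positions=",".join(c.name for c in data["chars"]),
            weight=float(data["weight"]),
        )
    nx.write_graphml(g, str(path))


def export_dot(net: HaploNetwork, path: str | Path) -> None:
    lines = ["graph haplonet {"]
    for node in sorted(net.graph.nodes):
        hap = net.haplotypes.get(node)
        if hap:
            label = f"{hap.label} (n={len(hap.members)})"
            shape = "circle"
        else:
            label = node
            shape = "point"
        if node == net.dca_node:
            label += " DCA"
        lines.append(f'  "{node}" [label="{label}", shape={shape}];')
    for u, v, data in sorted(net.graph.edges(data=True)):
        pos = ",".join(c.name for c in data["chars"])
        lines.append(f'  "{u}" -- "{v}" [label="{pos}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_nexus(
    aln: Alignment, haplotypes: list[Haplotype], path: str | Path
) -> None:
    """One representative full-length sequence per haplotype, NEXUS
    format, for use by external dating tools."""
    from Bio import AlignIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for hap in haplotypes:
        rep = hap.members[0]
        records.append(
            SeqRecord(
                Seq("".join(aln.row(rep))),
                id=f"{hap.haplotype_id}_{rep}",
                annotations={"molecule_type": "DNA"},
                description="",
            )
        )
    AlignIO.write(MultipleSeqAlignment(records), str(path), "nexus")
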