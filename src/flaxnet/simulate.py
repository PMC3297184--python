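"""Synthetic alignments with the statistical structure the pipeline
assumes: a haplotype genealogy carrying infinite-sites mutations, a
controlled number of repeat (homoplasious) mutations, optional
recombinant mosaic haplotypes, one multi-base indel segregating as a
single character, and group-structured sampling — plus a machine-
readable truth record from which the alignment can be replayed exactly.

Design notes
------------
* Every node of the genealogy is a sampled haplotype (extant ancestral
  states), mirroring networks in which ancestral haplotypes are still
  segregating.  The random topology is a uniform recursive tree: node i
  attaches to a uniformly chosen earlier node.
* A planted homoplasy is an exact repeat — same position, same derived
  base — placed on a branch that neither shares a node with nor is
  ancestrally related to the original branch.  Under that placement the
  repeat cannot be explained away by a single origin on the parsimony
  network, so planted counts are recoverable by homoplasy counting.
* Recombinant haplotypes are appended as extra nodes (never replacing a
  tree node), so the tree truth stays well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import Alignment, InputError

BASES = "ACGT"


@dataclass
class SimulationConfig:
    seed: int = 0
    L: int = 1000
    n_haplotypes: int = 8
    #: parent index per node; parents[0] must be -1 (root); None = random
    tree_parents: list[int] | None = None
    #: fixed integer, or ("poisson", mean)
    mutations_per_branch: int | tuple[str, float] = 2
    n_homoplasies: int = 0
    #: per-mutation repeat probability (alternative to the fixed count)
    homoplasy_prob: float = 0.0
    #: (parent1, parent2, breakpoint): mosaic = parent1[1..b] + parent2[b+1..L].
    #: A breakpoint of None picks the column that splits the parents'
    #: differences evenly, making the mosaic equidistant from both parents
    #: (the balanced configuration a parsimony network shows as a cycle).
    recombinants: list[tuple[int, int, int | None]] = field(default_factory=list)
    #: (start, length, carrier_node): gap run carried by the carrier's clade
    indel: tuple[int, int, int] | None = None
    samples_per_haplotype: int = 2
    #: explicit sampling plan: (group label, haplotype node, sample count)
    group_plan: list[tuple[str, int, int]] | None = None

    def validate(self) -> None:
        if self.n_haplotypes < 1:
            raise InputError("need at least one haplotype")
        if self.L < 1:
            raise InputError("L must be >= 1")
        if self.tree_parents is not None:
            if len(self.tree_parents) != self.n_haplotypes:
                raise InputError("tree_parents length must equal n_haplotypes")
            if self.tree_parents[0] != -1:
                raise InputError("tree_parents[0] must be -1 (root)")
            for i, p in enumerate(self.tree_parents[1:], start=1):
                if not (0 <= p < i):
                    raise InputError(f"tree_parents[{i}] must point to an earlier node")
        for p1, p2, b in self.recombinants:
            if b is not None and not (1 <= b <= self.L):
                raise InputError(f"breakpoint {b} outside 1..{self.L}")
            if p1 == p2:
                raise InputError("recombinant parents must differ")
        if self.indel is not None:
            start, length, carrier = self.indel
            if not (1 <= start and start + length - 1 <= self.L):
                raise InputError("indel outside the alignment")
            if not (0 <= carrier < self.n_haplotypes):
                raise InputError("indel carrier node out of range")
        if not (0.0 <= self.homoplasy_prob < 1.0):
            raise InputError("homoplasy_prob must be in [0, 1)")


@dataclass
class SimResult:
    alignment: Alignment
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fasta",
            "groups": outdir / "groups.tsv",
            "truth": outdir / "truth.json",
        }
        self.alignment.to_fasta(paths["fasta"])
        self.alignment.to_groups_tsv(paths["groups"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


def _ancestors(parents: list[int], node: int) -> set[int]:
    out = set()
    while parents[node] != -1:
        node = parents[node]
        out.add(node)
    return out


def _subtree(parents: list[int], node: int) -> set[int]:
    out = {node}
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(parents):
            if p in out and i not in out:
                out.add(i)
                changed = True
    return out


def _eligible_targets(parents: list[int], branch: int) -> list[int]:
    """Branches (child ids) on which a repeat of a mutation from
    ``branch`` remains detectable: no shared node, no ancestral relation."""
    out = []
    anc_b = _ancestors(parents, branch)
    nodes_b = {branch, parents[branch]}
    for c in range(1, len(parents)):
        if c == branch:
            continue
        if {c, parents[c]} & nodes_b:
            continue
        if c in anc_b or branch in _ancestors(parents, c):
            continue
        out.append(c)
    return out


def _has_four_gametes(rows: list[str], positions: list[int], b: int) -> bool:
    """True when some site pair straddling column b shows all four
    allele combinations among ``rows`` (gap-free biallelic sites only)."""
    bases = set(BASES)
    left = [p for p in positions if p <= b]
    right = [p for p in positions if p > b]
    for x in left:
        for y in right:
            combos = {
                (r[x - 1], r[y - 1])
                for r in rows
                if r[x - 1] in bases and r[y - 1] in bases
            }
            if len(combos) == 4:
                return True
    return False


def simulate(config: SimulationConfig) -> SimResult:
    """Generate an alignment, group table, and truth record.

    Deterministic for a fixed config (including the seed): identical
    configs give byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_haplotypes
    L = config.L

    if config.tree_parents is not None:
        parents = list(config.tree_parents)
    else:
        parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]

    # per-branch mutation counts
    if isinstance(config.mutations_per_branch, tuple):
        kind, mean = config.mutations_per_branch
        if kind != "poisson":
            raise InputError(f"unknown mutation model: {kind!r}")
        counts = [int(rng.poisson(mean)) for _ in range(1, n)]
    else:
        counts = [int(config.mutations_per_branch)] * (n - 1)

    indel_span: set[int] = set()
    if config.indel is not None:
        start, length, _ = config.indel
        indel_span = set(range(start, start + length))

    pool = [p for p in range(1, L + 1) if p not in indel_span]
    total = sum(counts)
    if total > len(pool):
        raise InputError("more mutations requested than available positions")
    positions = rng.choice(len(pool), size=total, replace=False)
    positions = [pool[i] for i in positions]

    root_seq = list(rng.choice(list(BASES), size=L))

    # mutations[branch child id] = list of (pos, derived)
    mutations: dict[int, list[tuple[int, str]]] = {c: [] for c in range(1, n)}
    flat: list[tuple[int, int, str]] = []  # (branch, pos, derived)
    cursor = 0
    for child in range(1, n):
        for _ in range(counts[child - 1]):
            pos = positions[cursor]
            cursor += 1
            others = [b for b in BASES if b != root_seq[pos - 1]]
            derived = str(rng.choice(others))
            mutations[child].append((pos, derived))
            flat.append((child, pos, derived))

    # planted homoplasies: exact repeats on detectably separated branches
    homoplasies: list[dict] = []

    def plant(branch: int, pos: int, derived: str) -> bool:
        targets = [
            t
            for t in _eligible_targets(parents, branch)
            if all(p != pos for p, _ in mutations[t])
        ]
        if not targets:
            return False
        target = int(targets[rng.integers(0, len(targets))])
        mutations[target].append((pos, derived))
        homoplasies.append(
            {"pos": pos, "derived": derived,
             "original_branch": branch, "repeat_branch": target}
        )
        return True

    if config.n_homoplasies:
        if not flat:
            raise InputError("cannot plant homoplasies without mutations")
        order = rng.permutation(len(flat))
        planted = 0
        for idx in order:
            if planted == config.n_homoplasies:
                break
            if plant(*flat[idx]):
                planted += 1
        if planted < config.n_homoplasies:
            raise InputError(
                f"only {planted} of {config.n_homoplasies} homoplasies "
                "could be planted on this topology"
            )
    if config.homoplasy_prob > 0:
        for branch, pos, derived in flat:
            if rng.random() < config.homoplasy_prob:
                plant(branch, pos, derived)

    truth = {
        "config": {
            "seed": config.seed, "L": L, "n_haplotypes": n,
            "mutations_per_branch": list(config.mutations_per_branch)
            if isinstance(config.mutations_per_branch, tuple)
            else config.mutations_per_branch,
        },
        "root_seq": "".join(root_seq),
        "tree_parents": parents,
        "edges": [
            {"child": c, "mutations": [{"pos": p, "derived": d} for p, d in mutations[c]]}
            for c in range(1, n)
        ],
        "homoplasies": homoplasies,
        "recombinants": [],
        "indel": None,
        "samples": [],
    }
    if config.indel is not None:
        start, length, carrier = config.indel
        truth["indel"] = {
            "start": start, "end": start + length - 1,
            "carrier_node": carrier,
            "carriers": sorted(_subtree(parents, carrier)),
        }

    # resolve recombinant breakpoints against the realised tree sequences
    tree_seqs = _node_sequences(truth)
    for i, (p1, p2, b) in enumerate(config.recombinants):
        if b is None:
            # balance in character space: the indel run counts as one
            # difference anchored at its start column
            diffs = [
                pos
                for pos in range(1, L + 1)
                if tree_seqs[p1][pos - 1] != tree_seqs[p2][pos - 1]
                and pos not in indel_span
            ]
            if config.indel is not None:
                ind = truth["indel"]
                if (p1 in ind["carriers"]) != (p2 in ind["carriers"]):
                    diffs.append(ind["start"])
                    diffs.sort()
            if len(diffs) < 2:
                raise InputError(
                    f"recombinant parents {p1}/{p2} differ at fewer than 2 sites"
                )
            # candidate breakpoints between consecutive differences, most
            # balanced first; prefer one whose mosaic creates a four-gamete
            # configuration among the realised node sequences (a split can
            # otherwise reconstruct an ancestral sequence and be invisible)
            cands = sorted(
                (abs(len(diffs) - 2 * i), (diffs[i - 1] + diffs[i]) // 2)
                for i in range(1, len(diffs))
            )
            b = None
            for _, b_cand in cands:
                if indel_span and min(indel_span) <= b_cand <= max(indel_span):
                    b_cand = max(indel_span)  # keep the gap run intact
                mosaic = tree_seqs[p1][:b_cand] + tree_seqs[p2][b_cand:]
                rows = [
                    "".join(s)
                    for s in list(tree_seqs.values()) + [mosaic]
                ]
                if _has_four_gametes(rows, diffs, b_cand):
                    b = b_cand
                    break
            if b is None:
                raise InputError(
                    f"no breakpoint makes the {p1}/{p2} recombinant "
                    "detectable (their differences do not interleave); "
                    "supply an explicit breakpoint or change the seed"
                )
        truth["recombinants"].append(
            {"node": n + i, "parent1": p1, "parent2": p2, "breakpoint": int(b)}
        )
        # later recombinants may use this node as a parent
        tree_seqs[n + i] = tree_seqs[p1][: int(b)] + tree_seqs[p2][int(b):]

    # sampling plan
    if config.group_plan is not None:
        plan = list(config.group_plan)
    else:
        n_total = n + len(config.recombinants)
        plan = [
            (f"g{node}", node, config.samples_per_haplotype)
            for node in range(n_total)
        ]
    for group, node, count in plan:
        for k in range(count):
            truth["samples"].append(
                {"sample_id": f"{group}_{node}_{k + 1}", "group": group, "node": node}
            )

    aln = replay(truth)
    truth["expected_haplotypes"] = _expected_haplotypes(aln)
    return SimResult(alignment=aln, truth=truth)


def _node_sequences(truth: dict) -> dict[int, list[str]]:
    parents = truth["tree_parents"]
    n = len(parents)
    seqs: dict[int, list[str]] = {0: list(truth["root_seq"])}
    muts = {e["child"]: e["mutations"] for e in truth["edges"]}
    for child in range(1, n):
        seq = list(seqs[parents[child]])
        for m in muts.get(child, []):
            seq[m["pos"] - 1] = m["derived"]
        seqs[child] = seq
    if truth["indel"] is not None:
        ind = truth["indel"]
        for node in ind["carriers"]:
            for pos in range(ind["start"], ind["end"] + 1):
                seqs[node][pos - 1] = "-"
    for rec in truth["recombinants"]:
        b = rec["breakpoint"]
        seqs[rec["node"]] = (
            seqs[rec["parent1"]][:b] + seqs[rec["parent2"]][b:]
        )
    return seqs


def replay(truth: dict) -> Alignment:
    """Reconstruct the exact alignment from a truth record (closure:
    simulate → truth → replay reproduces the emitted FASTA byte for
    byte)."""
    seqs = _node_sequences(truth)
    ids = [s["sample_id"] for s in truth["samples"]]
    rows = ["".join(seqs[s["node"]]) for s in truth["samples"]]
    groups = {s["sample_id"]: s["group"] for s in truth["samples"]}
    return Alignment.from_strings(ids, rows, groups)


def _expected_haplotypes(aln: Alignment) -> list[dict]:
    by_seq: dict[str, list[str]] = {}
    for sid, row in zip(aln.sample_ids, aln.seqs):
        by_seq.setdefault("".join(row), []).append(sid)
    return [
        {"members": members} for members in by_seq.values()
    ]


def paperlike_preset() -> SimulationConfig:
    """A fixed-seed configuration at the scale of a single-locus crop
    domestication survey: 113 samples over 11 haplotypes (one of them a
    recombinant mosaic), L = 2560, roughly forty substitutions, two
    planted repeat mutations, and one 46-bp indel carried by a wild +
    primitive-cultivated clade.  Wild groups are spread over more
    haplotypes than the bottlenecked cultivated groups."""
    #        0   1  2  3  4  5  6  7  8  9
    parents = [-1, 0, 0, 1, 1, 2, 2, 5, 6, 3]
    group_plan = [
        ("Lb-Turkey", 1, 8), ("Lb-Turkey", 3, 7), ("Lb-Turkey", 9, 5),
        ("Lb-Turkey", 5, 2), ("Lb-Turkey", 7, 2),
        ("Lb-Greece", 4, 4),
        ("Lb-other", 0, 9), ("Lb-other", 2, 6),
        ("Lu-o", 6, 10), ("Lu-o", 8, 6), ("Lu-o", 10, 4),
        ("Lu-f", 8, 10), ("Lu-f", 6, 7),
        ("Lu-w", 8, 10), ("Lu-w", 6, 6),
        ("Lu-n", 8, 9),
        ("Lu-d", 10, 8),
    ]
    return SimulationConfig(
        seed=1205,
        L=2560,
        n_haplotypes=10,
        tree_parents=parents,
        mutations_per_branch=4,
        n_homoplasies=2,
        recombinants=[(4, 2, None)],
        indel=(562, 46, 1),
        group_plan=group_plan,
    )


WILD_GROUPS = ("Lb-Turkey", "Lb-Greece", "Lb-other")
CULTIVATED_GROUPS = ("Lu-o", "Lu-f", "Lu-w", "Lu-n", "Lu-d")
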