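import itertools

import numpy as np
import pytest

from flaxnet.alignment import Alignment


def make_alignment(seqs, groups=None, ids=None):
    """Alignment from a list of sequence strings."""
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    groups = groups or {i: "g" for i in ids}
    return Alignment.from_strings(ids, seqs, groups)


def brute_force_pi(aln, gap_mode="pairwise"):
    """Independent double-loop oracle for per-site nucleotide diversity."""
    bases = set("ACGT")
    rows = ["".join(r) for r in aln.seqs]
    if gap_mode == "complete":
        keep = [
            j for j in range(aln.L) if all(r[j] in bases for r in rows)
        ]
        rows = ["".join(r[j] for j in keep) for r in rows]
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(rows, 2):
        valid = [(x, y) for x, y in zip(a, b) if x in bases and y in bases]
        m = len(valid)
        diffs = sum(1 for x, y in valid if x != y)
        total += diffs / m if m else 0.0
        npairs += 1
    return total / npairs if npairs else float("nan")


def brute_force_rm(aln):
    """Independent oracle for the four-gamete recombination lower bound:
    enumerate incompatible biallelic site pairs, then find the true
    maximum set of disjoint intervals by recursion (not the greedy
    scan used by the implementation)."""
    bases = set("ACGT")
    cols = {}
    for j in range(aln.L):
        col = [r[j] for r in aln.seqs]
        if any(c == "-" for c in col):
            continue
        obs = sorted({c for c in col if c in bases})
        if len(obs) == 2:
            cols[j + 1] = col
    pos = sorted(cols)
    pairs = []
    for a, b in itertools.combinations(pos, 2):
        gametes = {
            (x, y)
            for x, y in zip(cols[a], cols[b])
            if x in bases and y in bases
        }
        if len(gametes) == 4:
            pairs.append((a, b))

    def best(intervals):
        if not intervals:
            return []
        first, rest = intervals[0], intervals[1:]
        skip = best(rest)
        compatible = [iv for iv in rest if iv[0] >= first[1]]
        take = [first] + best(compatible)
        return take if len(take) > len(skip) else skip

    return len(best(sorted(pairs, key=lambda iv: (iv[1], iv[0]))))


@pytest.fixture
def rectangle_recombination():
    """Minimal four-gamete configuration: two parental haplotypes and a
    balanced mosaic child, each state present, so the network must show
    a reticulation cycle."""
    # sites:      12345678
    seqs = [
        "AAAAAAAA",  # root
        "CCAAAAAA",  # parent 1 (left mutations at 1, 2)
        "AAAACCAA",  # parent 2 (right mutations at 5, 6)
        "CCAACCAA",  # recombinant carrying both sides
    ]
    return make_alignment(
        seqs,
        ids=["root", "p1", "p2", "rec"],
        groups={"root": "wild", "p1": "wild", "p2": "wild", "rec": "cult"},
    )
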