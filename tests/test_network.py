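import networkx as nx
import numpy as np
import pytest

from flaxnet.alignment import InputError
from flaxnet.network import (
    build_network,
    collapse_haplotypes,
    count_homoplasies,
    export_dot,
    export_graphml,
    export_haplotype_table,
    export_nexus,
    identify_dca,
    roman,
)
from flaxnet.popgen import segregating_sites
from flaxnet.simulate import SimulationConfig, simulate

from conftest import make_alignment


def build_from(aln, indel_mode="include"):
    table = segregating_sites(aln)
    haps, cm = collapse_haplotypes(aln, table, indel_mode)
    return haps, cm, build_network(haps, cm.characters)


def test_roman_numerals():
    assert [roman(k) for k in (1, 4, 9, 11, 40)] == ["I", "IV", "IX", "XI", "XL"]


class TestCollapse:
    def test_three_state_vectors_with_membership(self):
        seqs = ["AAAA", "AAAA", "ACAA", "ACAA", "ACGA", "AAAA"]
        aln = make_alignment(seqs)
        haps, _ = collapse_haplotypes(aln, segregating_sites(aln))
        assert len(haps) == 3
        assert haps[0].members == ["s1", "s2", "s6"]
        assert haps[1].members == ["s3", "s4"]
        assert haps[2].members == ["s5"]
        assert [h.label for h in haps] == ["I", "II", "III"]

    def test_all_identical_single_haplotype(self):
        aln = make_alignment(["ACGT"] * 5)
        haps, _ = collapse_haplotypes(aln, segregating_sites(aln))
        assert len(haps) == 1 and len(haps[0].members) == 5

    def test_membership_conserves_sample_count(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("AC"), size=10)) for _ in range(12)]
        aln = make_alignment(seqs)
        haps, _ = collapse_haplotypes(aln, segregating_sites(aln))
        assert sum(len(h.members) for h in haps) == aln.n

    def test_indel_mode_separates_gap_haplotypes(self):
        seqs = ["AAAAA", "A--AA", "AAAAC", "A--AC"]
        aln = make_alignment(seqs)
        haps_with, _ = collapse_haplotypes(aln, segregating_sites(aln), "include")
        haps_without, _ = collapse_haplotypes(aln, segregating_sites(aln), "exclude")
        assert len(haps_with) == 4
        assert len(haps_without) == 2


class TestBuildNetwork:
    def test_single_haplotype_single_node(self):
        aln = make_alignment(["ACGT"] * 3)
        _, _, net = build_from(aln)
        assert net.graph.number_of_nodes() == 1
        assert net.m == 0

    def test_tree_data_reconstructs_tree(self):
        cfg = SimulationConfig(seed=11, L=300, n_haplotypes=7, mutations_per_branch=2)
        res = simulate(cfg)
        _, _, net = build_from(res.alignment)
        assert nx.is_tree(net.graph)
        # every planted mutation appears on exactly one edge
        h_net, per_char = count_homoplasies(net)
        assert h_net == 0 and per_char == {}
        planted = sum(len(e["mutations"]) for e in res.truth["edges"])
        assert net.m == planted

    def test_every_character_on_some_edge(self):
        cfg = SimulationConfig(seed=4, L=200, n_haplotypes=6, mutations_per_branch=2)
        res = simulate(cfg)
        _, cm, net = build_from(res.alignment)
        covered = set(net.char_edge_map())
        assert covered == {c.name for c in cm.characters}

    def test_rectangle_conflict_becomes_reticulation(self, rectangle_recombination):
        _, _, net = build_from(rectangle_recombination)
        assert not nx.is_tree(net.graph)
        cycles = net.reticulation_cycles()
        assert len(cycles) == 1 and len(cycles[0]) == 4
        h_net, per_char = count_homoplasies(net)
        # every one of the four conflicting sites sits on two edges
        assert h_net == 4
        assert all(len(edges) == 2 for edges in per_char.values())

    def test_planted_homoplasies_are_counted(self):
        cfg = SimulationConfig(
            seed=3, L=400, n_haplotypes=8, mutations_per_branch=2, n_homoplasies=2
        )
        res = simulate(cfg)
        _, _, net = build_from(res.alignment)
        h_net, per_char = count_homoplasies(net)
        assert h_net == 2
        planted = {str(h["pos"]) for h in res.truth["homoplasies"]}
        assert set(per_char) == planted

    def test_deterministic_exports(self, tmp_path):
        cfg = SimulationConfig(seed=9, L=250, n_haplotypes=6, mutations_per_branch=3)
        outputs = []
        for tag in ("a", "b"):
            res = simulate(cfg)
            _, _, net = build_from(res.alignment)
            p = tmp_path / f"{tag}.graphml"
            export_graphml(net, p)
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]


class TestIdentifyDCA:
    def test_star_ancestor_recovered(self):
        # planted ancestor haplotype surrounded by cultivated derivatives
        seqs = {
            "anc": "AAAAAA",
            "c1": "CAAAAA", "c2": "ACAAAA", "c3": "AACAAA", "c4": "AAACAA",
        }
        groups = {k: ("wild" if k == "anc" else "cult") for k in seqs}
        aln = make_alignment(list(seqs.values()), groups=groups, ids=list(seqs))
        haps, _, net = build_from(aln)
        dca, scores = identify_dca(net, ["cult"])
        anc_id = next(h.haplotype_id for h in haps if "anc" in h.members)
        assert dca == anc_id
        assert scores[dca] == min(scores.values())

    def test_single_node_network(self):
        aln = make_alignment(["ACGT"] * 2, groups={"s1": "cult", "s2": "cult"})
        _, _, net = build_from(aln)
        dca, _ = identify_dca(net, ["cult"])
        assert dca in net.graph.nodes

    def test_no_cultivated_samples_rejected(self):
        aln = make_alignment(["ACGT", "ACGA"])
        _, _, net = build_from(aln)
        with pytest.raises(InputError):
            identify_dca(net, ["cult"])


class TestExports:
    def test_haplotype_table_layout(self, tmp_path):
        import pandas as pd

        seqs = ["AACAA", "ACCAA", "AACAT"]
        aln = make_alignment(seqs)
        table = segregating_sites(aln)
        haps, _ = collapse_haplotypes(aln, table)
        out = tmp_path / "haps.tsv"
        export_haplotype_table(haps, table, aln, out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["sample", "group", "haplotype", "2", "5"]
        assert len(df) == 3

    def test_haplotype_table_no_sites(self, tmp_path):
        import pandas as pd

        aln = make_alignment(["AAA"] * 2)
        table = segregating_sites(aln)
        haps, _ = collapse_haplotypes(aln, table)
        out = tmp_path / "haps.tsv"
        export_haplotype_table(haps, table, aln, out)
        assert list(pd.read_csv(out, sep="\t").columns) == [
            "sample", "group", "haplotype",
        ]

    def test_dot_and_nexus_outputs(self, tmp_path, rectangle_recombination):
        from Bio import AlignIO

        haps, _, net = build_from(rectangle_recombination)
        export_dot(net, tmp_path / "n.dot")
        assert "--" in (tmp_path / "n.dot").read_text()
        export_nexus(rectangle_recombination, haps, tmp_path / "h.nex")
        nex = AlignIO.read(str(tmp_path / "h.nex"), "nexus")
        assert len(nex) == len(haps)
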