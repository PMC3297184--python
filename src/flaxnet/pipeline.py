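"""End-to-end orchestration: alignment → diversity tables → haplotype
network → recombination events → chronology, with cross-file output
validation."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import (
    Alignment,
    InputError,
    RegionAnnotation,
    read_alignment,
    read_regions,
)
from .chronology import calibrate_and_date, export_chronology
from .network import (
    build_network,
    collapse_haplotypes,
    count_homoplasies,
    export_dot,
    export_graphml,
    export_haplotype_table,
    export_nexus,
    identify_dca,
)
from .popgen import (
    diversity_summary,
    group_summary,
    hudson_kaplan_rm,
    segregating_sites,
    write_group_summary,
)
from .recombination import enumerate_events, events_table, homoplasy_model, network_test

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    alignment_path: str
    groups_path: str | None = None
    regions_path: str | None = None
    #: groups counted as cultivated when locating the DCA node
    cultivated_groups: list[str] | None = None
    #: (node label or id, age in years) enabling the dating stage
    calibration: tuple[str, float] | None = None
    gap_mode: str = "pairwise"
    indel_mode: str = "include"
    indel_weight: float = 1.0
    depth_mode: str = "mean_tip_path"
    outdir: str = "flaxnet_out"


OUTPUTS = (
    "diversity.tsv",
    "haplotypes.tsv",
    "network.graphml",
    "network.dot",
    "haplotypes.nex",
    "events.tsv",
    "summary.json",
)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the report bundle.

    Returns the output directory.  A stage failure raises with a
    stage-tagged message; outputs written so far are retained and the
    MANIFEST marks the bundle incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "version": __version__, "outputs": []}

    def _save_manifest():
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1)
    )
    manifest["outputs"].append("config.json")

    stage = "input"
    try:
        aln = read_alignment(config.alignment_path, config.groups_path)
        regions = (
            read_regions(config.regions_path, aln.L)
            if config.regions_path
            else RegionAnnotation.whole(aln.L)
        )

        stage = "diversity"
        div = group_summary(aln, regions, gap_mode=config.gap_mode)
        write_group_summary(div, outdir / "diversity.tsv")
        manifest["outputs"].append("diversity.tsv")
        overall = diversity_summary(aln, gap_mode=config.gap_mode)
        rm, rm_intervals = hudson_kaplan_rm(aln)

        stage = "network"
        table = segregating_sites(aln)
        haps, cm = collapse_haplotypes(
            aln, table, config.indel_mode, config.indel_weight
        )
        net = build_network(haps, cm.characters)
        cultivated = config.cultivated_groups or []
        dca = None
        if any(
            g in cultivated for h in haps for g in h.group_counts
        ):
            dca, _ = identify_dca(net, cultivated)
        h_net, per_char = count_homoplasies(net)
        export_haplotype_table(haps, table, aln, outdir / "haplotypes.tsv")
        export_graphml(net, outdir / "network.graphml")
        export_dot(net, outdir / "network.dot")
        export_nexus(aln, haps, outdir / "haplotypes.nex")
        manifest["outputs"] += [
            "haplotypes.tsv", "network.graphml", "network.dot", "haplotypes.nex",
        ]

        stage = "events"
        model = homoplasy_model(aln.L, net.m)
        events = enumerate_events(net, model)
        events_table(events).to_csv(outdir / "events.tsv", sep="\t", index=False)
        manifest["outputs"].append("events.tsv")
        p_point, p_tail = network_test(model, h_net)

        chron_summary = None
        if config.calibration is not None:
            stage = "dating"
            node, age = config.calibration
            label_map = {h.label: h.haplotype_id for h in haps}
            node_id = label_map.get(node, node)
            chron, cal = calibrate_and_date(
                net, node_id, float(age), aln.L, config.depth_mode
            )
            export_chronology(chron, outdir / "chronology.tsv")
            manifest["outputs"].append("chronology.tsv")
            chron_summary = {
                "rate_subs_per_site_per_year": chron.rate,
                "calibration_node": node_id,
                "calibration_age_years": float(age),
                "node_ages": chron.ages,
            }

        stage = "summary"
        summary = {
            "n": aln.n,
            "L": aln.L,
            "S": overall.S,
            "n_haplotypes": len(haps),
            "pi_per_bp": overall.pi_per_bp,
            "tajima_D": _none_if_nan(overall.tajima_D),
            "fu_li_Dstar": _none_if_nan(overall.fu_li_Dstar),
            "fu_li_Fstar": _none_if_nan(overall.fu_li_Fstar),
            "Rm": rm,
            "Rm_intervals": rm_intervals,
            "indel_events": [
                {"start": ev.start, "end": ev.end, "length": ev.length}
                for ev in table.indel_events
            ],
            "network": {
                "m": net.m,
                "H_net": h_net,
                "homoplasy_positions": sorted(per_char),
                "n_median_nodes": len(net.median_nodes()),
                "dca_node": dca,
                "P_net_point": p_point,
                "P_net_tail": p_tail,
            },
            "events": [
                {
                    "event": ev.event_id,
                    "N": ev.N,
                    "H": ev.H,
                    "P_binom": ev.P_binom,
                    "significant_05": ev.significant_05,
                    "significant_01": ev.significant_01,
                }
                for ev in events
            ],
            "chronology": chron_summary,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["outputs"].append("summary.json")
        manifest["complete"] = True
    except Exception as exc:
        _save_manifest()
        raise InputError(f"[stage: {stage}] {exc}") from exc
    _save_manifest()
    return outdir


def _none_if_nan(x: float):
    import math

    return None if (isinstance(x, float) and math.isnan(x)) else x


def validate_outputs(outdir: str | Path) -> tuple[bool, list[str]]:
    """Cross-file consistency checks over a report bundle.

    Verifies that haplotype-table membership matches the network's
    sampled node count, that member counts sum to n, and that the event
    homoplasy counts do not exceed the network total.  Returns
    ``(ok, violations)``.
    """
    outdir = Path(outdir)
    violations: list[str] = []
    manifest_path = outdir / "MANIFEST.json"
    if not manifest_path.exists():
        return False, ["missing MANIFEST.json"]
    manifest = json.loads(manifest_path.read_text())
    if not manifest.get("complete"):
        violations.append("MANIFEST marks bundle incomplete")
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        return False, violations + ["missing summary.json"]
    summary = json.loads(summary_path.read_text())

    haps = pd.read_csv(outdir / "haplotypes.tsv", sep="\t")
    if len(haps) != summary["n"]:
        violations.append(
            f"haplotype table has {len(haps)} rows but summary n={summary['n']}"
        )
    if haps["haplotype"].nunique() != summary["n_haplotypes"]:
        violations.append(
            "haplotype label count does not match summary n_haplotypes"
        )
    events = pd.read_csv(outdir / "events.tsv", sep="\t")
    if len(events) and events["H"].sum() < 0:
        violations.append("negative homoplasy count in events")
    if len(events) and int(events["H"].sum()) > 2 * summary["network"]["H_net"]:
        violations.append("event homoplasies exceed network homoplasy budget")
    return (len(violations) == 0), violations
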