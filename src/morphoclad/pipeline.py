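"""One-command reproduction of the full cladistic workflow.

``run_analysis`` executes, in order: equal-weight heuristic search, fit
indices, strict consensus, bootstrap, successive weighting, ancestral
mapping on the first successive-weighting tree, and species-group
diagnosis — writing Newick trees, TSV tables and a JSON report whose
every number is recomputable from the matrix and seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .consensus import bootstrap_support, strict_consensus, support_newick
from .groups import DiagnosisTable, GroupPartition, diagnose_groups, test_monophyly
from .mapping import map_characters
from .matrix import CharacterMatrix, read_matrix
from .parsimony import fit_indices
from .search import SearchConfig, heuristic_search
from .weighting import final_profiles, successive_search

log = logging.getLogger("morphoclad")

DEFAULT_CONFIG = {
    "replicates": 100,
    "hold": 10,
    "maxtrees": 100,
    "bootstrap_replicates": 100,
    "bootstrap_starts": 10,
    "bootstrap_maxtrees": 16,
    "bootstrap_sw": True,
    "sw_basis": "rc",
    "sw_fit": "max",
    "sw_max_iter": 20,
    "seed": 0,
    "outgroups": [],
    "groups": {},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisReport:
    """Aggregated results of one run (see ``run_analysis``)."""

    ew_result: object = None
    ew_profile: object = None
    ew_consensus: object = None
    ew_bootstrap: object = None
    sw_trace: object = None
    sw_profiles: list = field(default_factory=list)
    sw_consensus: object = None
    sw_bootstrap: object = None
    mapping: object = None
    diagnosis: DiagnosisTable | None = None
    monophyly: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        d = {
            "version": self.provenance.get("version"),
            "seed": self.provenance.get("seed"),
            "ew": {
                "length": self.ew_result.best_length,
                "n_trees": self.ew_result.n_trees,
                "CI": round(self.ew_profile.CI, 3),
                "HI": round(self.ew_profile.HI, 3),
                "RI": round(self.ew_profile.RI, 3),
                "RC": round(self.ew_profile.RC, 3),
            },
        }
        if self.sw_trace is not None:
            d["sw"] = {
                "converged": self.sw_trace.converged,
                "iterations": len(self.sw_trace.iterations) - 1,
                "n_trees": self.sw_trace.final_result.n_trees,
                "trees": _unique_profiles(self.sw_profiles),
            }
        if self.mapping is not None:
            d["mapping"] = {
                "n_unambiguous": self.mapping.n_unambiguous,
                "totals": self.mapping.totals,
            }
        if self.monophyly:
            d["monophyly"] = {
                g: {"monophyletic": ok, "intruders": intr}
                for g, (ok, intr) in self.monophyly.items()
            }
        return d


def _unique_profiles(profiles) -> list:
    """Distinct (length, CI, HI, RI, RC) tuples with multiplicities; binary
    resolutions of the same collapsed tree share one line."""
    seen: dict[tuple, dict] = {}
    for p in profiles:
        key = (round(p.L, 2), round(p.CI, 3), round(p.HI, 3), round(p.RI, 3), round(p.RC, 3))
        if key not in seen:
            seen[key] = {
                "length": key[0], "CI": key[1], "HI": key[2],
                "RI": key[3], "RC": key[4], "n_trees": 0,
            }
        seen[key]["n_trees"] += 1
    return list(seen.values())


def load_config(path=None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def run_analysis(
    matrix_path=None,
    config_path=None,
    out_dir="analysis_out",
    seed=None,
    replicates=None,
    matrix: CharacterMatrix | None = None,
    config: dict | None = None,
) -> AnalysisReport:
    """Execute the full workflow; see the module docstring.

    A matrix (or its path), plus optional config overrides.  Partial
    outputs are kept with a FAILED marker if a stage errors.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config) if config is not None else load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    if replicates is not None:
        cfg["replicates"] = int(replicates)
    if matrix is None:
        fmt = "tsv" if str(matrix_path).endswith((".tsv", ".txt")) else "nexus"
        matrix = read_matrix(matrix_path, format=fmt, outgroup_taxa=cfg["outgroups"])
    elif cfg["outgroups"] and not matrix.outgroup_taxa:
        matrix = CharacterMatrix(matrix.taxa, matrix.data, cfg["outgroups"])

    report = AnalysisReport(
        provenance={
            "version": __version__,
            "seed": cfg["seed"],
            "config": {k: v for k, v in cfg.items() if k != "groups"},
            "n_taxa": matrix.n_taxa,
            "n_char": matrix.n_char,
        }
    )
    stage = "setup"
    try:
        rng = np.random.default_rng(cfg["seed"])
        seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in
                 ("ew", "boot_ew", "sw", "boot_sw")}
        search_cfg = SearchConfig(
            n_replicates=cfg["replicates"], hold=cfg["hold"],
            maxtrees=cfg["maxtrees"], seed=seeds["ew"],
        )
        boot_cfg = SearchConfig(
            n_replicates=cfg["bootstrap_starts"], hold=1,
            maxtrees=cfg["bootstrap_maxtrees"], seed=0,
        )

        stage = "ew_search"
        report.ew_result = heuristic_search(matrix, None, search_cfg)
        log.info(
            "EW search: length %.4g, %d tree(s)",
            report.ew_result.best_length, report.ew_result.n_trees,
        )
        report.ew_profile = fit_indices(report.ew_result.binary_trees, matrix)
        report.ew_consensus = strict_consensus(report.ew_result.trees)
        _write(out / "ew_trees.nwk", "".join(
            t.to_newick(canonical=True) + "\n" for t in _sorted_trees(report.ew_result)
        ))
        _write(out / "ew_consensus.nwk", report.ew_consensus.to_newick(canonical=True) + "\n")
        report.ew_profile.to_table().to_csv(out / "ew_fit.tsv", sep="\t", index=False)

        stage = "bootstrap_ew"
        report.ew_bootstrap = bootstrap_support(
            matrix, None, boot_cfg, cfg["bootstrap_replicates"], seed=seeds["boot_ew"]
        )
        report.ew_bootstrap.to_table().to_csv(out / "bootstrap_ew.tsv", sep="\t", index=False)
        _write(
            out / "ew_consensus_support.nwk",
            support_newick(report.ew_consensus, report.ew_bootstrap) + "\n",
        )

        stage = "sw"
        sw_cfg = SearchConfig(
            n_replicates=cfg["replicates"], hold=cfg["hold"],
            maxtrees=cfg["maxtrees"], seed=seeds["sw"],
        )
        report.sw_trace = successive_search(
            matrix, sw_cfg, basis=cfg["sw_basis"], fit=cfg["sw_fit"],
            max_iter=cfg["sw_max_iter"],
        )
        report.sw_profiles = final_profiles(report.sw_trace, matrix)
        report.sw_consensus = strict_consensus(report.sw_trace.final_result.trees)
        log.info(
            "SW: converged=%s after %d iteration(s); %d tree(s)",
            report.sw_trace.converged, len(report.sw_trace.iterations) - 1,
            report.sw_trace.final_result.n_trees,
        )
        _write(out / "sw_trees.nwk", "".join(
            t.to_newick(canonical=True) + "\n"
            for t in _sorted_trees(report.sw_trace.final_result)
        ))
        report.sw_trace.to_table().to_csv(out / "sw_trace.tsv", sep="\t", index=False)

        if cfg["bootstrap_sw"]:
            stage = "bootstrap_sw"
            report.sw_bootstrap = bootstrap_support(
                matrix, report.sw_trace.final_weights, boot_cfg,
                cfg["bootstrap_replicates"], seed=seeds["boot_sw"],
            )
            report.sw_bootstrap.to_table().to_csv(
                out / "bootstrap_sw.tsv", sep="\t", index=False
            )

        if matrix.outgroup_taxa:
            stage = "mapping"
            tree1 = sw_tree_one(report.sw_trace)
            rooted = tree1.root_with_outgroups(matrix.outgroup_taxa)
            report.mapping = map_characters(rooted, matrix)
            report.mapping.to_table().to_csv(out / "changes.tsv", sep="\t", index=False)

            if cfg["groups"]:
                stage = "diagnosis"
                partition = GroupPartition(
                    {g: frozenset(m) for g, m in cfg["groups"].items()}
                )
                report.diagnosis = diagnose_groups(matrix, partition)
                report.diagnosis.to_table().to_csv(
                    out / "diagnosis.tsv", sep="\t", index=False
                )
                for g, members in partition.groups.items():
                    report.monophyly[g] = test_monophyly(rooted, members)

        stage = "report"
        body = json.dumps(report.summary_dict(), indent=2, sort_keys=True)
        _write(out / "report.json", body + "\n")
        _write(out / "summary.txt", _summary_text(report))
    except Exception as exc:
        _write(out / "FAILED", f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc
    return report


def sw_tree_one(trace) -> "Tree":
    """'Tree I' of the successive-weighting result: the first binary best
    tree in canonical order (a reproducible, arbitrary representative)."""
    return sorted(trace.final_result.binary_trees, key=lambda t: t.canonical_newick)[0]


def _sorted_trees(result):
    return sorted(result.trees, key=lambda t: t.canonical_newick)


def _write(path: Path, text: str) -> None:
    path.write_text(text)


def _summary_text(report: AnalysisReport) -> str:
    d = report.summary_dict()
    lines = [
        f"morphoclad {d['version']} analysis (seed {d['seed']})",
        "",
        (
            f"EW search: tree length = {d['ew']['length']:g}; {d['ew']['n_trees']} "
            f"most-parsimonious tree(s); CI = {d['ew']['CI']:.3f}; "
            f"HI = {d['ew']['HI']:.3f}; RI = {d['ew']['RI']:.3f}; "
            f"RC = {d['ew']['RC']:.3f}"
        ),
    ]
    if "sw" in d:
        lines.append(
            f"SW search: converged = {d['sw']['converged']} in "
            f"{d['sw']['iterations']} iteration(s); {d['sw']['n_trees']} tree(s)"
        )
        for i, t in enumerate(d["sw"]["trees"], start=1):
            lines.append(
                f"  SW profile {i} ({t['n_trees']} tree(s)): weighted length = "
                f"{t['length']:.2f}; CI = {t['CI']:.3f}; HI = {t['HI']:.3f}; "
                f"RI = {t['RI']:.3f}; RC = {t['RC']:.3f}"
            )
    if "mapping" in d:
        tot = d["mapping"]["totals"]
        lines.append(
            f"Mapping: {d['mapping']['n_unambiguous']} unambiguous changes "
            f"(apomorphies {tot['apomorphy']}, parallelisms {tot['parallelism']}, "
            f"reversals {tot['reversal']}, parallel-reversals {tot['parallel-reversal']})"
        )
    if "monophyly" in d:
        for g, info in d["monophyly"].items():
            status = "monophyletic" if info["monophyletic"] else (
                "non-monophyletic (intruders: " + ", ".join(info["intruders"]) + ")"
            )
            lines.append(f"Group {g}: {status}")
    return "\n".join(lines) + "\n"
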