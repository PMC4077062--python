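"""End-to-end orchestration of the analysis stages from a single config.

The pipeline wires the stages together: conservation-contrast candidate
selection from a labelled alignment, topology annotation, structural
filtering on a supplied model, uptake-kinetics fitting, and phenotype
classification. Every stage can be toggled; disabling one never alters
another's numeric outputs. Every parameter actually used is written to the
run log so the configurable defaults stay auditable, and a manifest of the
files written is produced even on partial failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import conservation, kinetics, phenotype, structure, topology
from .containers import UptakeDataset

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

DEFAULT_PARAMS: dict[str, Any] = {
    "probe_radius": 2.0,  # Å; cavity-surface probe (water probe 1.4 available)
    "n_sphere_points": 960,
    "exposure_threshold": 0.15,
    "mode": "identity",
    "paralogue_rule": "not_all",
    "family_scope": "all",
    "fold_threshold": 1.5,
    "salt_bridge_cutoff": 4.0,
    "initial_rate_window": 2.0,
    "seed": 0,
}

DEFAULT_STAGES = ("conserve", "topology", "structure", "kinetics", "classify")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, parameters and stage toggles for one pipeline run."""

    output_dir: Path
    inputs: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        toggles = {name: True for name in DEFAULT_STAGES}
        toggles.update(self.stages)
        self.stages = toggles

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            output_dir=raw.get("output_dir", "ureakit_out"),
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
            stages=raw.get("stages", {}) or {},
        )


def _require_input(cfg: PipelineConfig, stage: str, key: str) -> Path:
    value = cfg.inputs.get(key)
    if not value:
        raise StageError(stage, f"required input {key!r} missing from config")
    path = Path(value)
    if not path.exists():
        raise StageError(stage, f"input {key!r} not found: {path}")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages; return the manifest of written outputs.

    On a stage failure a :class:`StageError` is raised after the manifest
    (covering the stages that did complete) has been written.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"outputs": {}, "stages_run": [], "failed_stage": None}
    log_lines = ["parameters used:"]
    for key in sorted(cfg.params):
        log_lines.append(f"  {key} = {cfg.params[key]}")
    log_lines.append(f"stages enabled: {[s for s, on in cfg.stages.items() if on]}")

    def _write(name: str, frame: pd.DataFrame, stem: str) -> None:
        tsv = out / f"{stem}.tsv"
        frame.to_csv(tsv, sep="\t")
        manifest["outputs"][name] = str(tsv)

    family_candidates = None
    try:
        if cfg.stages.get("conserve"):
            stage = "conserve"
            aln_path = _require_input(cfg, stage, "alignment")
            gmap_path = _require_input(cfg, stage, "group_map")
            aln = conservation.read_alignment(aln_path, conservation.read_group_map(gmap_path))
            directed = conservation.select_directed_candidates(
                aln, mode=cfg.params["mode"], paralogue_rule=cfg.params["paralogue_rule"]
            )
            family_candidates = conservation.select_family_conserved(
                aln, scope=cfg.params["family_scope"], mode=cfg.params["mode"]
            )
            topo = None
            if cfg.stages.get("topology"):
                topo_path = _require_input(cfg, "topology", "topology")
                topo = topology.read_topology(topo_path)
                directed = topology.annotate_candidates(topo, directed)
                family_candidates = topology.annotate_candidates(topo, family_candidates)
                manifest["stages_run"].append("topology")

            def _frame(cands):
                return pd.DataFrame(
                    [
                        {
                            "ref_position": c.ref_position,
                            "ref_residue": c.ref_residue,
                            "class": c.conservation_class,
                            "topology": c.topology_label if c.topology_label else "n.d.",
                        }
                        for c in cands
                    ]
                ).set_index("ref_position") if cands else pd.DataFrame(
                    columns=["ref_residue", "class", "topology"]
                )

            _write("directed_candidates", _frame(directed), "directed_candidates")
            _write("family_conserved", _frame(family_candidates), "family_conserved")
            manifest["stages_run"].append(stage)

        if cfg.stages.get("structure"):
            stage = "structure"
            pdb_path = _require_input(cfg, stage, "structure")
            model = structure.read_structure(pdb_path)
            sasa_result = structure.sasa(
                model,
                probe_radius=cfg.params["probe_radius"],
                n_sphere_points=cfg.params["n_sphere_points"],
            )
            sasa_frame = pd.DataFrame(
                {
                    "residue": list(sasa_result.per_residue_total),
                    "total_A2": list(sasa_result.per_residue_total.values()),
                    "sidechain_A2": list(sasa_result.per_residue_sidechain.values()),
                    "relative_sidechain": list(sasa_result.relative_sidechain.values()),
                }
            ).set_index("residue")
            _write("sasa", sasa_frame, "sasa_per_residue")
            bridges = structure.find_salt_bridges(model, cutoff=cfg.params["salt_bridge_cutoff"])
            bridge_frame = pd.DataFrame(
                [
                    {
                        "basic_residue": b.basic_residue,
                        "basic_name": b.basic_name,
                        "acidic_residue": b.acidic_residue,
                        "acidic_name": b.acidic_name,
                        "min_atom_distance_A": b.min_atom_distance,
                    }
                    for b in bridges
                ]
            )
            _write("salt_bridges", bridge_frame, "salt_bridges")
            if family_candidates is not None:
                result = structure.pathway_candidates(
                    model, sasa_result, family_candidates, threshold=cfg.params["exposure_threshold"]
                )
                pw = pd.DataFrame(
                    [
                        {"ref_position": c.ref_position, "ref_residue": c.ref_residue, "status": "candidate"}
                        for c in result.candidates
                    ]
                    + [
                        {"ref_position": c.ref_position, "ref_residue": c.ref_residue, "status": "unevaluable"}
                        for c in result.unevaluable
                    ]
                )
                _write("pathway_candidates", pw, "pathway_candidates")
            manifest["stages_run"].append(stage)

        if cfg.stages.get("kinetics"):
            stage = "kinetics"
            specs = cfg.inputs.get("uptake") or []
            if not specs:
                raise StageError(stage, "no uptake datasets listed under inputs.uptake")
            rows = []
            for entry in specs:
                path = Path(entry["path"])
                if not path.exists():
                    raise StageError(stage, f"uptake table not found: {path}")
                kind = entry["kind"]
                ds = UptakeDataset.from_tsv(path, kind=kind, tracer_conc=entry.get("tracer_conc"))
                row: dict[str, Any] = {"dataset": path.name, "kind": kind, "condition": ds.condition}
                if kind == "saturation":
                    res = kinetics.fit_michaelis_menten(ds)
                    row.update(Km_uM=res.Km, Km_se=res.Km_se, Vmax=res.Vmax, Vmax_se=res.Vmax_se,
                               converged=res.converged, reliable=res.reliable)
                elif kind == "competition":
                    res = kinetics.fit_ic50(ds)
                    row.update(IC50_uM=str(res.IC50), IC50_se=res.IC50_se, V0=res.V0,
                               censored=res.censored, converged=res.converged)
                    km_ref = entry.get("Km_uM")
                    if km_ref and res.tracer_conc:
                        row["Ki_uM"] = str(res.ki(float(km_ref)))
                elif kind == "timecourse":
                    rate = kinetics.initial_rate(ds, window=cfg.params["initial_rate_window"])
                    row.update(rate=rate.value, rate_se=rate.se, n_replicates=rate.n_replicates)
                else:
                    raise StageError(stage, f"unknown uptake dataset kind {kind!r}")
                rows.append(row)
            _write("kinetic_fits", pd.DataFrame(rows).set_index("dataset"), "kinetic_fits")
            manifest["stages_run"].append(stage)

        if cfg.stages.get("classify"):
            stage = "classify"
            allele_path = cfg.inputs.get("alleles")
            if allele_path:
                table = pd.read_csv(allele_path, sep="\t", dtype=str).set_index("allele")
            else:
                from .datasets import load_allele_table

                table = load_allele_table()
            records = phenotype.records_from_table(table)
            classified = phenotype.classify_table(
                records, fold_threshold=cfg.params["fold_threshold"]
            )
            _write("phenotypes", classified, "phenotype_classes")
            manifest["stages_run"].append(stage)
    except StageError as err:
        manifest["failed_stage"] = err.stage
        raise
    finally:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
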