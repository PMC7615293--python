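"""End-to-end pipeline: identity -> clustering -> activity -> mining -> calibration.

A :class:`PipelineConfig` (YAML-serialisable) names the input files and the
thresholds; :func:`run_pipeline` executes every stage for which inputs are
present, writing each intermediate artifact plus a ``manifest.json`` with
the configuration echo, input checksums, package version and timestamps.
A stage failure leaves a ``FAILED`` marker naming the stage and re-raises.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import activity as activity_mod
from . import calibrate as calibrate_mod
from . import cluster as cluster_mod
from . import orthomine
from . import seqid
from .errors import PipelineStageError, PylorthoError


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full analysis run.

    Thresholds default to the values used throughout the analysis:
    synthetase clusters are cut at 55% identity, tRNA clusters at 75%, and
    mutually orthogonal sets require cognate activity > 40%, cross
    reactivity < 20% and an orthogonality coefficient > 2.5.
    """

    synthetase_alignment: Optional[str] = None
    trna_alignment: Optional[str] = None
    activity_table: Optional[str] = None
    metadata_table: Optional[str] = None
    cognate_map: Optional[dict] = None  # tRNA id -> synthetase id

    synthetase_identity_threshold: float = 55.0
    trna_identity_threshold: float = 75.0
    min_cognate: float = 40.0
    max_cross: float = 20.0
    min_oc: float = 2.5
    orders: list = field(default_factory=lambda: [2, 3, 4, 5])
    identity_convention: str = "coverage"
    activity_cutoff: float = 20.0
    allow_heterologous: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "synthetase_identity_threshold",
            "trna_identity_threshold",
            "min_cognate",
            "max_cross",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise PylorthoError(f"{name}={v} outside [0, 100]")
        if not self.min_oc > 1:
            raise PylorthoError(f"min_oc must be > 1, got {self.min_oc}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all configured stages, returning the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "inputs": {},
        "outputs": [],
    }
    for name in (
        "synthetase_alignment",
        "trna_alignment",
        "activity_table",
        "metadata_table",
    ):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    def emit(name: str):
        manifest["outputs"].append(name)

    stage = "identity"
    try:
        criteria = orthomine.OrthogonalityCriteria(
            config.min_cognate, config.max_cross, config.min_oc
        )
        synth_ident = trna_ident = None
        if config.synthetase_alignment:
            aln = seqid.read_aligned_fasta(config.synthetase_alignment, "protein")
            synth_ident = seqid.identity_matrix(
                aln, convention=config.identity_convention
            )
            synth_ident.write_tsv(out / "synthetase_identity.tsv")
            emit("synthetase_identity.tsv")
        if config.trna_alignment:
            aln = seqid.read_aligned_fasta(config.trna_alignment, "nucleotide")
            trna_ident = seqid.identity_matrix(
                aln, convention=config.identity_convention
            )
            trna_ident.write_tsv(out / "trna_identity.tsv")
            emit("trna_identity.tsv")

        stage = "cluster"
        for ident, label, thr in (
            (synth_ident, "synthetase", config.synthetase_identity_threshold),
            (trna_ident, "trna", config.trna_identity_threshold),
        ):
            if ident is None:
                continue
            tree = cluster_mod.upgma_tree(ident)
            cluster_mod.write_newick(tree, out / f"{label}_tree.nwk")
            assignment = cluster_mod.clusters_at_identity(tree, thr)
            reps = cluster_mod.cluster_representatives(assignment, ident)
            cluster_mod.write_cluster_table(
                assignment, out / f"{label}_clusters.tsv", reps
            )
            emit(f"{label}_tree.nwk")
            emit(f"{label}_clusters.tsv")

        stage = "activity"
        m = None
        if config.activity_table:
            m = activity_mod.load_activity_table(config.activity_table)
            activity_mod.write_validation_report(m, out / "activity_report.json")
            m.write_tsv(out / "activity_matrix.tsv")
            emit("activity_report.json")
            emit("activity_matrix.tsv")

        stage = "mine"
        if m is not None:
            summary = {}
            for order in config.orders:
                sets = orthomine.enumerate_orthogonal_sets(
                    m,
                    order,
                    criteria,
                    allow_heterologous=config.allow_heterologous,
                    cognate_map=config.cognate_map,
                )
                fams = orthomine.group_into_families(sets)
                orthomine.write_sets_tsv(
                    sets, out / f"orthogonal_sets_order{order}.tsv", fams
                )
                emit(f"orthogonal_sets_order{order}.tsv")
                summary[order] = {
                    "count": len(sets),
                    "family_count": len(fams),
                    "max_oc": max((s.oc for s in sets), default=None),
                }
            orthomine.write_summary_json(summary, out / "mining_summary.json")
            emit("mining_summary.json")

        stage = "calibrate"
        if m is not None and config.cognate_map and synth_ident is not None:
            points = calibrate_mod.build_identity_activity_points(
                m, synth_ident, trna_ident, config.cognate_map, axis="synthetase"
            )
            calibrate_mod.write_points_tsv(points, out / "calibration_points.tsv")
            grid = list(range(0, 100, 5))
            curve = calibrate_mod.scan_thresholds(
                points, config.activity_cutoff, grid
            )
            curve.to_frame().to_csv(
                out / "calibration_curve.tsv", sep="\t", index=False
            )
            emit("calibration_points.tsv")
            emit("calibration_curve.tsv")

        stage = "manifest"
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineStageError(stage, str(exc)) from exc
    return out
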