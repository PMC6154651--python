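"""Orchestration of the full library-design funnel.

parse → validate → drug-likeness filter → structural alerts → fingerprint →
cluster → pick representatives → esterify → (external docking) → rank.

One root seed fans out to per-stage seeds through a documented derivation
(``numpy.random.SeedSequence(root).generate_state(3) mod 2**31`` for the
synthetic-library, clustering and representative draws, in that order), so
any stage can also be rerun independently from the manifest. Every artifact
is plain text (TSV/CSV/SMILES/JSON) and contains no timestamps: rerunning a
manifest reproduces the artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic_data
from .chem_core import parse_structures, write_smiles_tsv
from .curation import (
    FilterCriteria,
    FunnelReport,
    apply_alerts,
    apply_druglike_filter,
    load_alert_catalogue,
    validate_library,
)
from .diversity import FingerprintSpec, cluster, fingerprint, select_representatives
from .enumeration import enumerate_library, load_default_scaffold, products_to_csv
from .screening_rank import (
    DockingConfig,
    control_check,
    load_scores,
    rank_ligands,
    ranked_to_csv,
)

__all__ = ["PipelineConfig", "PipelineResult", "derive_seeds", "run_pipeline"]

logger = logging.getLogger(__name__)


def derive_seeds(root_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(root_seed).generate_state(3)
    names = ("synthetic", "clustering", "representative")
    return {name: int(s % 2**31) for name, s in zip(names, state)}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; round-trips through the manifest losslessly."""

    seed: int = 0
    input_smiles: str | None = None  # path; None → generate synthetically
    synthetic: dict = field(
        default_factory=lambda: {"n": 2000, "fraction_property_pass": 0.175}
    )
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    fingerprint_spec: FingerprintSpec = field(default_factory=FingerprintSpec)
    k: int = 285
    threshold: float | None = None
    top_n: int = 5
    scores_csv: str | None = None
    docking: DockingConfig = field(default_factory=DockingConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["docking"] = self.docking.to_manifest()
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        d["criteria"] = FilterCriteria(**d["criteria"])
        d["fingerprint_spec"] = FingerprintSpec(**d["fingerprint_spec"])
        docking = dict(d["docking"])
        docking["grid_points"] = tuple(docking["grid_points"])
        d["docking"] = DockingConfig(**docking)
        return PipelineConfig(**d)


@dataclass
class PipelineResult:
    out_dir: Path
    funnel: FunnelReport
    counts: dict[str, int]
    manifest_path: Path


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending ids."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg.seed)
    counts: dict[str, int] = {}

    # --- input library -----------------------------------------------------
    if cfg.input_smiles is not None:
        text = Path(cfg.input_smiles).read_text()
    else:
        spec = synthetic_data.LibrarySpec(seed=seeds["synthetic"], **cfg.synthetic)
        records = synthetic_data.generate_library(spec)
        text = synthetic_data.records_to_smi(records)
        (out / "labels.tsv").write_text(
            synthetic_data.records_to_labels_tsv(records)
        )
    (out / "library.smi").write_text(text)

    try:
        parsed = parse_structures(text, "smiles")
    except Exception as exc:
        raise PipelineError("parse", str(exc)) from exc
    counts["parsed"] = len(parsed.molecules)
    counts["parse_rejects"] = len(parsed.rejects)

    # --- curation funnel ---------------------------------------------------
    funnel = FunnelReport()
    valid, _, stage0 = validate_library(list(parsed.molecules))
    funnel.add(stage0)
    druglike, _, stage1 = apply_druglike_filter(valid, cfg.criteria)
    funnel.add(stage1)
    alerts = load_alert_catalogue()
    curated, _, stage2 = apply_alerts(druglike, alerts)
    funnel.add(stage2)
    (out / "funnel.tsv").write_text(funnel.to_tsv())
    counts["curated"] = len(curated)
    if not curated:
        raise PipelineError("curation", "no molecules survive the funnel")

    # --- diversity selection ----------------------------------------------
    fps = [fingerprint(m, cfg.fingerprint_spec) for m in curated]
    if cfg.threshold is not None:
        assignment = cluster(fps, threshold=cfg.threshold, seed=seeds["clustering"])
    else:
        assignment = cluster(fps, k=cfg.k, seed=seeds["clustering"])
    rep_ids = select_representatives(assignment, seeds["representative"])
    assignment = assignment.with_representatives(rep_ids)
    (out / "clusters.tsv").write_text(assignment.to_tsv())
    (out / "representatives.txt").write_text("\n".join(rep_ids) + "\n")
    counts["clusters"] = assignment.n_nonempty
    counts["representatives"] = len(rep_ids)

    # --- enumeration -------------------------------------------------------
    site = load_default_scaffold()
    by_id = {m.id: m for m in curated}
    products, ester_rejects = enumerate_library(
        site, [by_id[i] for i in rep_ids]
    )
    (out / "esters.smi").write_text(
        write_smiles_tsv([p.product for p in products])
    )
    (out / "esters.csv").write_text(products_to_csv(products))
    if ester_rejects:
        (out / "ester_rejects.tsv").write_text(
            "".join(f"{i}\t{reason}\n" for i, reason in ester_rejects)
        )
    counts["esters"] = len(products)
    counts["ester_rejects"] = len(ester_rejects)

    # --- external scores, if provided --------------------------------------
    if cfg.scores_csv is not None:
        try:
            records = load_scores(Path(cfg.scores_csv).read_text())
        except Exception as exc:
            raise PipelineError("rank", str(exc)) from exc
        ranked = rank_ligands(records, top_n=None)
        (out / "ranked.csv").write_text(ranked_to_csv(ranked))
        report = control_check(records)
        (out / "control_check.txt").write_text(
            report.status + "\n" + "\n".join(report.messages) + "\n"
        )
        counts["ranked"] = len(ranked)

    manifest = {
        "config": cfg.to_dict(),
        "seeds": seeds,
        "counts": counts,
        "funnel": [
            {
                "stage": s.name,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "rejections": dict(sorted(s.rejections.items())),
            }
            for s in funnel.stages
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %s", counts)
    return PipelineResult(out, funnel, counts, manifest_path)
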