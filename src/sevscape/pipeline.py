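"""End-to-end orchestration with a single validated config.

PipelineConfig collects every knob of the staged analysis (simulation,
thresholds, split ratio, seeds, stage toggles) and rejects unknown keys
so typos fail before anything runs. run_all executes
synthesize → pair-differential → lost-signature → source-tracing →
gene-sets → diagnostics, writing each stage's artifacts under out_dir,
stamped with the config hash and seed. With a fixed config the run is
deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import diagpanel, genesets, ioformats, lostsig, pairdiff, sourcetrace, synth
from .containers import SCHEMA_VERSION

log = logging.getLogger("sevscape")

_STAGES = ("simulate", "pairdiff", "lost", "trace", "enrich", "diagnose")


@dataclass
class PipelineConfig:
    simulation: dict[str, Any] = field(default_factory=dict)
    fc: float = 1.5
    alpha: float = 0.05
    min_support: int = 4
    detection_floor: int = 5
    caf_floor_cpm: float = 1.0
    caf_min_samples: int | None = None
    detect_min: int = 6
    detect_floor: float = 1.0
    ratio: float = 0.7
    cv_folds: int = 5
    seed: int = 0
    out_dir: str = "sevscape_out"
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    gmt: str | None = None
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def violations(self) -> list[str]:
        out = []
        if not 0 < self.alpha < 1:
            out.append(f"alpha={self.alpha} must be in (0,1)")
        if self.fc <= 0:
            out.append(f"fc={self.fc} must be positive")
        if self.min_support < 1:
            out.append(f"min_support={self.min_support} must be ≥ 1")
        if not 0 < self.ratio < 1:
            out.append(f"ratio={self.ratio} must be in (0,1)")
        if self.cv_folds < 2:
            out.append(f"cv_folds={self.cv_folds} must be ≥ 2")
        if self.detect_min < 1:
            out.append(f"detect_min={self.detect_min} must be ≥ 1")
        if self.caf_floor_cpm < 0:
            out.append(f"caf_floor_cpm={self.caf_floor_cpm} must be ≥ 0")
        bad_stages = set(self.stages) - set(_STAGES)
        if bad_stages:
            out.append(f"unknown stage(s): {sorted(bad_stages)}")
        try:
            sim = self.simulation_config()
        except synth.ConfigurationError as exc:
            out.append(f"simulation: {exc}")
        else:
            if self.min_support > sim.n_patients:
                out.append(
                    f"min_support={self.min_support} exceeds n_patients={sim.n_patients}"
                )
            if self.detect_min > sim.n_patients:
                out.append(
                    f"detect_min={self.detect_min} exceeds n_patients={sim.n_patients}"
                )
        return out

    def simulation_config(self) -> synth.SimulationConfig:
        known = {f.name for f in dataclasses.fields(synth.SimulationConfig)}
        unknown = set(self.simulation) - known
        if unknown:
            raise synth.ConfigurationError(
                f"unknown simulation key(s): {sorted(unknown)}"
            )
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        cfg = synth.SimulationConfig(**kwargs)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        # out_dir is a deployment detail, not part of the run's identity
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def validate_config(path: str | Path) -> list[str]:
    """Load a YAML/JSON config and list every violation (empty = valid)."""
    raw = ioformats.read_config(path)
    try:
        cfg = PipelineConfig.from_mapping(raw)
    except (TypeError, ValueError) as exc:
        return [str(exc)]
    return cfg.violations()


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run every enabled stage on a synthetic cohort; return a result bundle.

    Each stage writes its artifacts under out_dir; the returned dict holds
    the in-memory results keyed by stage name.
    """
    problems = config.violations()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    sim = config.simulation_config()
    bundle: dict[str, Any] = {"config_hash": chash}

    def stamp(d: dict) -> dict:
        d["config_hash"] = chash
        d["seed"] = config.seed
        return d

    log.info("stage=simulate seed=%d hash=%s", config.seed, chash)
    sc_counts, labels, reference, ref_truth = synth.simulate_reference(sim)
    cohort, truth = synth.simulate_paired_cohort(sim, reference)
    bundle["truth"] = truth
    bundle["cohort"] = cohort
    if "simulate" in config.stages:
        for src in ("T", "N", "O", "B", "CAF"):
            m = synth.subset_by_source(cohort, src)
            ioformats.write_matrix_tsv(m, out_dir / f"counts_{src}.tsv")
        ioformats.write_metadata_tsv(cohort.metadata.values(), out_dir / "samples.tsv")
        ioformats.write_mtx_triplet(sc_counts.T, out_dir / "reference")
        labels.to_frame().to_csv(out_dir / "reference" / "clusters.tsv", sep="\t")
        ioformats.write_report(stamp(truth.to_dict()), out_dir / "ground_truth.json")

    patients = sorted({m.patient_id for m in cohort.metadata.values() if m.source == "T"})
    t_contrasts = {}
    o_contrasts = {}
    if {"pairdiff", "lost", "trace"} & set(config.stages):
        log.info("stage=pairdiff seed=%d hash=%s", config.seed, chash)
        for pid in patients:
            t_contrasts[pid] = pairdiff.per_patient_contrast(
                cohort, pid, "T", "N", fc_threshold=config.fc, alpha=config.alpha,
                detection_floor=config.detection_floor,
            )
            o_contrasts[pid] = pairdiff.per_patient_contrast(
                cohort, pid, "O", "N", fc_threshold=config.fc, alpha=config.alpha,
                detection_floor=config.detection_floor,
            )
        signature = pairdiff.majority_vote(
            list(t_contrasts.values()), config.min_support, name="cancer_specific"
        )
        bundle["signature"] = signature
        if "pairdiff" in config.stages:
            for pid, res in t_contrasts.items():
                ioformats.write_differential_tsv(res, out_dir / f"diff_{pid}_T_vs_N.tsv")
            ioformats.write_report(stamp(signature.to_dict()), out_dir / "signature.json")

    if "lost" in config.stages:
        log.info("stage=lost seed=%d hash=%s", config.seed, chash)
        caf_matrix = synth.subset_by_source(cohort, "CAF")
        lost = lostsig.build_lost_signature(
            t_contrasts,
            o_contrasts,
            caf_matrix=caf_matrix,
            min_support=config.min_support,
            caf_min_samples=config.caf_min_samples,
            caf_floor_cpm=config.caf_floor_cpm,
        )
        bundle["lost"] = lost
        ioformats.write_report(stamp(lost.to_dict()), out_dir / "lost_signature.json")

    if "trace" in config.stages:
        log.info("stage=trace seed=%d hash=%s", config.seed, chash)
        sig = sourcetrace.build_signature(sc_counts, labels, m=sim.markers_per_cluster)
        bulk = synth.subset_by_source(cohort, "T").values.sum(axis=1)
        deg = t_contrasts[patients[0]] if t_contrasts else None
        attribution = sourcetrace.trace(
            bulk, sig, reference.cell_counts, deg=deg, immune=reference.immune
        )
        bundle["attribution"] = attribution
        ioformats.write_report(stamp(attribution.to_dict()), out_dir / "attribution.json")
        attribution.per_cluster.to_csv(out_dir / "attribution.tsv", sep="\t")

    if "enrich" in config.stages and "signature" in bundle:
        log.info("stage=enrich seed=%d hash=%s", config.seed, chash)
        universe = set(cohort.feature_ids)
        if config.gmt:
            sets = ioformats.read_gmt(config.gmt)
        else:
            # no collection supplied: score the planted truth sets, which
            # doubles as a recovery read-out
            sets = {
                "planted_tumor_up": {"description": "planted", "members": truth.tumor_up_genes},
                "planted_lost": {"description": "planted", "members": truth.lost_genes},
            }
        query = bundle["signature"].members & universe
        enr = genesets.ora(query, sets, universe)
        bundle["enrichment"] = enr
        ioformats.write_report(stamp(enr.to_dict()), out_dir / "enrichment.json")

    if "diagnose" in config.stages:
        log.info("stage=diagnose seed=%d hash=%s", config.seed, chash)
        diag_matrix, diag_truth = synth.simulate_diagnostic_cohort(sim)
        labels_map = {
            s: 1 if m.group == "case" else 0 for s, m in diag_matrix.metadata.items()
        }
        panel = sorted(diag_truth.diagnostic_markers)
        report = diagpanel.train_signature(
            diag_matrix,
            labels_map,
            panel,
            ratio=config.ratio,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        report.per_gene_auc = diagpanel.per_gene_auc(diag_matrix, labels_map, panel)
        bundle["diagnostic"] = report
        bundle["diagnostic_truth"] = diag_truth
        ioformats.write_report(stamp(report.to_dict()), out_dir / "diagnostic.json")

    return bundle
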