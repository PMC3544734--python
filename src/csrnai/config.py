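"""Pipeline configuration, format glue and the end-to-end driver.

The screening pipeline runs four progressive stages: motif ingest and
consensus extraction, effective-siRNA classification, sensing-matrix design
(with pruning), and sparse signal recovery / simulation. ``run_pipeline``
ties them together from a validated YAML-loadable configuration and writes
a manifest recording seeds, input hashes and every output path. All
randomness flows from the single configured seed through named substreams,
one per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier_selection import LabeledRecord, make_datasets, predict, svm_rfe, train
from .motif_network import (
    build_sensing_matrix,
    coherence_report,
    prune_network,
    read_occurrences,
)
from .sirna_features import extract_psf_rules, feature_matrix, load_nn_table, PSFRule
from .screen_simulation import SimulationConfig, run_sweep
from .synthetic_data import ActivityRuleSpec, paper_scale_fixture, synth_sirna_activity

logger = logging.getLogger("csrnai")


def configure_logging(level: int = logging.INFO) -> None:
    """Structured stage logs on standard error; results never go there."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _stage_seed(seed: int, stage: int) -> int:
    return int(_substream(seed, stage).integers(2 ** 31))


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    Unknown keys are rejected at load time; every stochastic stage derives
    its seed from the single global ``seed``.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    occurrence_table: str | None = None   # None -> synthesize the fixture
    training_table: str | None = None     # None -> synthesize labeled records
    cutoffs: tuple[float, float] = (0.4, 0.6)
    svm_C: float = 1.0
    folds: int = 5
    rfe_enabled: bool = False
    rfe_step_fraction: float = 0.1
    ngsk_decay: float = 0.5
    prune_modal_fraction: float = 0.8
    simulate: bool = False
    sim_sparsity_levels: tuple = (3,)
    sim_sigmas: tuple = (0.001,)
    sim_reps: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("cutoffs", "sim_sparsity_levels", "sim_sigmas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# TSV / CSV format glue
# ---------------------------------------------------------------------------

def write_rules(rules, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tpattern\tdirection\tp_value\n")
        for r in rules:
            fh.write(f"{r.position}\t{r.pattern}\t{r.direction}\t{r.p_value:.6e}\n")


def read_rules(path) -> list[PSFRule]:
    df = pd.read_csv(path, sep="\t")
    return [
        PSFRule(int(r.position), str(r.pattern), str(r.direction), float(r.p_value))
        for r in df.itertuples()
    ]


def write_model(model, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bias\t{model.bias:.12e}\n")
        names = model.feature_names or [f"f{i}" for i in range(len(model.weights))]
        for name, w in zip(names, model.weights):
            fh.write(f"{name}\t{w:.12e}\n")


def read_records(path) -> list[LabeledRecord]:
    """Labeled training records from TSV (id, sequence, activity)."""
    df = pd.read_csv(path, sep="\t")
    return [
        LabeledRecord(str(r.id), str(r.sequence), float(r.activity))
        for r in df.itertuples()
    ]


def write_records(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\tactivity\n")
        for r in records:
            fh.write(f"{r.record_id}\t{r.sequence}\t{r.activity:.6f}\n")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the four-stage pipeline and write artifacts plus a manifest.

    Stages: (1) occurrence ingest and consensus extraction; (2) rule
    learning, feature extraction and effective-siRNA classification of the
    candidate consensus sequences; (3) pruning and sensing-matrix assembly
    with a coherence report; (4) optional recovery simulation sweep.
    Returns the manifest dictionary (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages": {},
    }

    # -- stage 1: occurrences and consensus sequences ----------------------
    logger.info("stage=ingest seed=%d", config.seed)
    if config.occurrence_table:
        occ_path = Path(config.occurrence_table)
        manifest["inputs"]["occurrence_table"] = _sha256(occ_path)
        profiles = read_occurrences(occ_path)
    else:
        _, truth = paper_scale_fixture(seed=_stage_seed(config.seed, 1))
        occ_path = out / "occurrences.tsv"
        truth.to_csv(occ_path, sep="\t", index=False)
        manifest["outputs"]["occurrence_table"] = str(occ_path)
        profiles = read_occurrences(occ_path)
    if not profiles:
        raise ValueError("stage ingest: empty occurrence table")
    manifest["stages"]["ingest"] = {"n_motifs": len(profiles)}

    # -- stage 2: rule learning and candidate classification ---------------
    logger.info("stage=classify")
    if config.training_table:
        manifest["inputs"]["training_table"] = _sha256(config.training_table)
        records = read_records(config.training_table)
    else:
        spec = ActivityRuleSpec(
            psf_terms=[(1, "A", 2.0), (19, "T", 2.0), (10, "G", -2.0)],
            thermo_weight=0.1,
            noise_sd=0.5,
            n_records=300,
            seed=_stage_seed(config.seed, 2),
        )
        records, _ = synth_sirna_activity(spec)
        write_records(records, out / "training_records.tsv")
        manifest["outputs"]["training_table"] = str(out / "training_records.tsv")
    dataset = make_datasets(records, cutoff_sets=(config.cutoffs,))[0]
    positives = [r.sequence for r in dataset.records if r.label == 1]
    negatives = [r.sequence for r in dataset.records if r.label == -1]
    psf_rules = extract_psf_rules(positives, negatives, mode="single", k=20)
    spsf_rules = extract_psf_rules(positives, negatives, mode="dinucleotide", k=16)
    write_rules(psf_rules, out / "psf_rules.tsv")
    write_rules(spsf_rules, out / "spsf_rules.tsv")
    nn = load_nn_table()
    X, names = feature_matrix(dataset.sequences, psf_rules, spsf_rules, nn=nn,
                              ngsk_decay=config.ngsk_decay)
    y = dataset.labels
    columns = None
    if config.rfe_enabled:
        rfe = svm_rfe(X, y, step_fraction=config.rfe_step_fraction,
                      folds=config.folds, seed=_stage_seed(config.seed, 3),
                      C=config.svm_C)
        columns = rfe.selected
        pd.DataFrame(
            {"n_features": rfe.n_features_path, "cv_accuracy": rfe.cv_accuracy_path}
        ).to_csv(out / "rfe_path.csv", index=False)
        manifest["outputs"]["rfe_path"] = str(out / "rfe_path.csv")
        X_fit = X[:, columns]
        fit_names = [names[i] for i in columns]
    else:
        X_fit, fit_names = X, list(names)
    model = train(X_fit, y, C=config.svm_C, feature_names=fit_names)
    write_model(model, out / "model.tsv")
    candidates = [p.mcs for p in profiles]
    Xc, _ = feature_matrix(candidates, psf_rules, spsf_rules, nn=nn,
                           ngsk_decay=config.ngsk_decay)
    if columns is not None:
        Xc = Xc[:, columns]
    labels, margins = predict(model, Xc)
    n_pos = int(np.sum(labels == 1))
    assert n_pos + int(np.sum(labels == -1)) == len(candidates)
    manifest["stages"]["classify"] = {
        "n_candidates": len(candidates),
        "n_effective": n_pos,
        "n_rejected": len(candidates) - n_pos,
    }
    effective = {p.motif_id for p, lab in zip(profiles, labels) if lab == 1}
    kept = [p for p in profiles if p.motif_id in effective]
    if not kept:
        raise ValueError("stage classify: no candidate called effective")

    # -- stage 3: pruning and sensing-matrix assembly ----------------------
    logger.info("stage=matrix n_motifs=%d", len(kept))
    pruned, audit = prune_network(kept, seed=_stage_seed(config.seed, 4),
                                  max_modal_fraction=config.prune_modal_fraction)
    audit.write(out / "prune_audit.txt")
    matrix = build_sensing_matrix(pruned)
    matrix.write_mtx(str(out / "sensing_matrix"))
    matrix.write_sif(out / "network.sif")
    report = coherence_report(matrix)
    manifest["stages"]["matrix"] = {
        "shape": list(matrix.shape),
        "m_phi": report.m_phi,
        "pair_count": report.pair_count,
        "zero_pairs": report.zero_pairs,
    }
    manifest["outputs"].update(
        {
            "sensing_matrix": str(out / "sensing_matrix.mtx"),
            "network_sif": str(out / "network.sif"),
            "prune_audit": str(out / "prune_audit.txt"),
        }
    )
    if matrix.shape[0] >= matrix.shape[1]:
        logger.warning("matrix is not compressive: m=%d >= n=%d", *matrix.shape)

    # -- stage 4: optional recovery simulation -----------------------------
    if config.simulate:
        logger.info("stage=simulate")
        sim = SimulationConfig(
            m=matrix.shape[0],
            n=matrix.shape[1],
            sparsity_levels=config.sim_sparsity_levels,
            sigmas=config.sim_sigmas,
            reps=config.sim_reps,
            seed=_stage_seed(config.seed, 5),
        )
        sweep = run_sweep(matrix, sim)
        sweep.to_csv(out / "sweep.csv", index=False)
        manifest["outputs"]["sweep"] = str(out / "sweep.csv")
        manifest["stages"]["simulate"] = {
            "rows": len(sweep),
            "mean_mse": float(sweep["mse"].mean()),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
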