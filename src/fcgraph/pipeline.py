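"""End-to-end orchestration: QC -> connectome -> metrics -> GLM
(-> behavioral), from one config and one master seed, with a
provenance manifest.

All randomness lives in synthetic generation and permutation sampling;
the master seed fans out to fixed per-stage child seeds so each stage
is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .behavioral import standardized_ols
from .connectome import apply_weight_scheme, build_connectome
from .glm import PermutationResult, build_design, run_permutation_glm
from .metrics import GLOBAL_METRICS, NODAL_METRICS, compute_all_metrics
from .motion import compute_fd, flag_frames, qc_report, select_participants
from .parcellation import Parcellation
from .synthetic import CohortConfig, simulate_cohort_data

log = logging.getLogger("fcgraph")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Cohort-generation settings plus analysis-stage options."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    weight_scheme: str = "abs"
    model: str = "base"
    n_perm: int = 1000
    fd_threshold: float = 0.5
    max_flagged_fraction: float = 0.40
    runs_required: int = 4

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        raw.pop("seed", None)
        pipeline_keys = {
            "weight_scheme", "model", "n_perm", "fd_threshold",
            "max_flagged_fraction", "runs_required",
        }
        pl = {k: raw.pop(k) for k in list(raw) if k in pipeline_keys}
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            cfg = CohortConfig.from_dict(cohort)
        elif raw:
            cfg = CohortConfig.from_dict(raw)
        else:
            cfg = CohortConfig()
        return cls(cohort=cfg, **pl)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    inclusion: pd.DataFrame
    qc: pd.DataFrame
    metric_tables: dict[str, pd.DataFrame]
    glm_results: dict[str, PermutationResult]
    manifest: dict


def _child_seed(master: int, *tags: int) -> int:
    return int(np.random.SeedSequence([int(master), *tags]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def compute_metric_tables(
    graphs: Mapping[str, np.ndarray], parcellation: Parcellation
) -> dict[str, pd.DataFrame]:
    """Participants x nodes tables for every nodal metric and
    participants x 1 tables for the global ones."""
    records: dict[str, dict] = {m: {} for m in (*NODAL_METRICS, *GLOBAL_METRICS)}
    for pid, g in graphs.items():
        vals = compute_all_metrics(g, parcellation)
        for m in NODAL_METRICS:
            records[m][pid] = vals[m]
        for m in GLOBAL_METRICS:
            records[m][pid] = [vals[m]]
    tables = {}
    for m in NODAL_METRICS:
        tables[m] = pd.DataFrame.from_dict(
            records[m], orient="index", columns=list(parcellation.parcel_ids)
        )
    for m in GLOBAL_METRICS:
        tables[m] = pd.DataFrame.from_dict(records[m], orient="index", columns=[m])
    return tables


def run_pipeline(
    config: PipelineConfig | CohortConfig,
    seed: int,
    out_dir: str | Path | None = None,
    metrics: tuple[str, ...] | None = None,
    run_behavioral: bool = True,
) -> PipelineResult:
    """Simulate a cohort and run QC, connectome construction, graph
    metrics, permutation GLM and behavioral statistics.

    Any participant excluded at QC is absent from every later stage.
    Identical (config, seed) reproduces identical outputs; when
    ``out_dir`` is given, all stage outputs are written as TSV/JSON and
    checksummed into the run manifest.
    """
    if isinstance(config, CohortConfig):
        config = PipelineConfig(cohort=config)
    t0 = time.time()
    manifest: dict = {
        "package_version": _version,
        "seed": int(seed),
        "config": {
            "cohort": asdict(config.cohort) | {
                "behavioral_coefficients": dict(config.cohort.behavioral_coefficients),
                "designated_nodes": list(config.cohort.designated_nodes),
                "age_range": list(config.cohort.age_range),
            },
            "weight_scheme": config.weight_scheme,
            "model": config.model,
            "n_perm": config.n_perm,
            "fd_threshold": config.fd_threshold,
            "max_flagged_fraction": config.max_flagged_fraction,
            "runs_required": config.runs_required,
        },
        "started_unix": t0,
        "stages": {},
        "checksums": {},
    }
    parc = config.cohort.parcellation()

    log.info("stage simulate: generating cohort (N=%d)", config.cohort.n_participants)
    cohort, truth, timeseries, motion = simulate_cohort_data(
        config.cohort, _child_seed(seed, 1)
    )
    manifest["stages"]["simulate"] = {"n_participants": len(cohort)}

    log.info("stage qc: framewise displacement and exclusion rules")
    masks = {
        pid: {
            f"run{r + 1}": flag_frames(compute_fd(tr), config.fd_threshold)
            for r, tr in enumerate(traces)
        }
        for pid, traces in motion.items()
    }
    qc = qc_report(masks, config.max_flagged_fraction)
    inclusion = select_participants(masks, config.runs_required, config.max_flagged_fraction)
    cohort = cohort.merge(inclusion[["participant_id", "mean_fd", "retained"]],
                          on="participant_id")
    retained = cohort[cohort["retained"]].drop(columns=["retained"]).reset_index(drop=True)
    if retained.empty:
        raise ValueError("motion QC excluded every participant; nothing to analyse")
    manifest["stages"]["qc"] = {
        "n_retained": len(retained),
        "n_excluded": int(len(cohort) - len(retained)),
    }
    log.info("stage qc: retained %d of %d participants", len(retained), len(cohort))

    log.info("stage build: connectomes (%s weighting)", config.weight_scheme)
    graphs = {}
    for pid in retained["participant_id"]:
        cm = build_connectome(timeseries[pid])
        graphs[pid] = apply_weight_scheme(cm, config.weight_scheme)
    manifest["stages"]["build"] = {"n_connectomes": len(graphs)}

    log.info("stage metrics: %d graphs", len(graphs))
    tables = compute_metric_tables(graphs, parc)
    if metrics is not None:
        tables = {m: tables[m] for m in metrics}

    log.info("stage glm: %d metrics, %d permutations", len(tables), config.n_perm)
    design = build_design(retained, model=config.model)
    glm_results = {}
    for mi, (mname, table) in enumerate(sorted(tables.items())):
        glm_results[mname] = run_permutation_glm(
            table, design, n_perm=config.n_perm, seed=_child_seed(seed, 2, mi)
        )
    manifest["stages"]["glm"] = {
        "model": config.model,
        "n_perm": config.n_perm,
        "n_dropped_rows": design.n_dropped,
        "metrics": sorted(tables),
    }

    if run_behavioral:
        log.info("stage behavioral: socio-demographic regression")
        reg = standardized_ols(retained)
        manifest["stages"]["behavioral"] = {
            "n_used": reg.n_used,
            "r2_adj": reg.r2_adj,
        }
    else:
        reg = None

    manifest["elapsed_s"] = time.time() - t0

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
        truth.to_json(out / "ground_truth.json")
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        inclusion.to_csv(out / "inclusion.tsv", sep="\t", index=False)
        for mname, table in tables.items():
            table.to_csv(out / f"metric_{mname}.tsv", sep="\t")
        for mname, res in glm_results.items():
            res.to_tsv(out / f"glm_{mname}.tsv", metric_name=mname)
        if reg is not None:
            reg.coefficients.to_csv(out / "behavioral_regression.tsv", sep="\t", index=False)
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["checksums"][f.name] = _sha256(f)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        cohort=cohort,
        inclusion=inclusion,
        qc=qc,
        metric_tables=tables,
        glm_results=glm_results,
        manifest=manifest,
    )
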