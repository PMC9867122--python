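"""End-to-end pipeline orchestration with seeded reproducibility.

Stages run in order — simulate, score, rank, aggregate, benchmark, gi50,
synergy, qpcr — each reading and writing only the documented plain-text file
formats (no hidden state), so any stage can be re-run or inspected in
isolation.  A run manifest records the SHA-256 checksum of every artifact;
identical config + seed gives bit-identical checksums, and a rerun over an
output directory whose manifest already validates skips the cached stages.

One global seed fans out to per-stage seeds derived by hashing the stage
name (CRC-32), so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from drugsig import io
from drugsig.benchmark import benchmark, random_control
from drugsig.datatypes import PanelDefinition
from drugsig.doseresponse import (
    combination_potency_shifts,
    fit_gi50,
    normalize_inhibition,
)
from drugsig.qpcr import ddct_analysis
from drugsig.scoring import PROTOCOLS, build_matrix
from drugsig.signatures import aggregate_multi_query, rank_against_query
from drugsig.simulate import (
    LibraryConfig,
    generate_combination_table,
    generate_ct_table,
    generate_dose_response,
    generate_world,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

STAGES = ("simulate", "score", "rank", "aggregate", "benchmark", "gi50", "synergy", "qpcr")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _default_validation() -> dict:
    return {
        "gi50": {"planted_gi50": 12.54, "hill": 1.0, "top": 100.0, "bottom": 0.0,
                 "doses": [0.1, 0.32, 1.0, 3.2, 10.0, 32.0, 100.0, 316.0],
                 "n_reps": 3, "noise_sd": 5.0, "dilution": "log", "drug": "osimertinib"},
        "synergy": {"drug_a": "ARS-1620", "drug_b": "osimertinib",
                    "params_a": {"gi50": 500.0, "hill": 1.0},
                    "params_b": {"gi50": 12.5, "hill": 1.0},
                    "doses_a": [0.32, 1.0, 3.2, 10.0, 32.0],
                    "doses_b": [1.0, 3.2, 10.0],
                    "bliss_excess": 25.0, "n_reps": 3, "noise_sd": 2.0},
        "qpcr": {"fold_changes": {"combination": {"KRAS": 0.5, "DUSP-6": 0.25}},
                 "reference_condition": "untreated", "noise_sd": 0.1, "n_reps": 3},
    }


@dataclass
class RunConfig:
    """Versioned configuration of a full pipeline run (JSON-serialisable)."""

    schema_version: int = SCHEMA_VERSION
    library: dict = field(default_factory=dict)  # LibraryConfig overrides
    protocol: str = "product"
    panel: object = "human"  # "human" or an explicit list of protein ids
    queries: list = field(default_factory=list)  # explicit query compound ids
    auto_queries: int = 2  # if no explicit queries: first k members of the first indication
    candidates: list = field(default_factory=list)
    auto_candidates: int = 5  # if no explicit candidates: top-k of each query's ranking
    cutoffs: list = field(default_factory=lambda: [10, 25, 50, 100])
    random_control_reps: int = 200
    validation: dict = field(default_factory=_default_validation)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {self.schema_version}")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be sorted ascending")
        known_lib = set(LibraryConfig.__dataclass_fields__) - {"seed"}
        unknown = set(self.library) - known_lib
        if unknown:
            raise ValueError(f"unknown library config keys: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:  # silent typos are the main reproducibility hazard
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed offset by a CRC-32 hash of the stage name."""
    return int((global_seed + zlib.crc32(stage.encode())) % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> dict:
    """Execute all stages and return the run manifest.

    ``force=True`` ignores any cached artifacts.  The manifest maps each
    stage to the checksums of its artifacts; rerunning with the same config
    and seed reproduces the checksums bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    manifest_path = out / "manifest.json"
    old_manifest = None
    if manifest_path.exists() and not force:
        try:
            candidate = json.loads(manifest_path.read_text())
            if candidate.get("config_hash") == config.config_hash():
                old_manifest = candidate
        except (json.JSONDecodeError, KeyError):
            old_manifest = None

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def cached(stage: str, artifacts: list) -> bool:
        if old_manifest is None or stage not in old_manifest.get("stages", {}):
            return False
        recorded = old_manifest["stages"][stage]["artifacts"]
        if set(recorded) != {str(a) for a in artifacts}:
            return False
        for rel, digest in recorded.items():
            p = out / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(stage: str, artifacts: list) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "artifacts": {str(a): _sha256(out / a) for a in artifacts},
        }

    def run_stage(stage: str, artifacts: list, fn) -> None:
        if cached(stage, artifacts):
            logger.info("stage %s: cached, skipping", stage)
            manifest["stages"][stage] = old_manifest["stages"][stage]
            return
        logger.info("stage %s: running", stage)
        try:
            fn(stage_seed(config.seed, stage))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        record(stage, artifacts)

    # ---- simulate ----------------------------------------------------
    def do_simulate(seed):
        lib = LibraryConfig(**config.library, seed=seed)
        world = generate_world(lib)
        io.write_compounds(world.compounds, out / "compounds.tsv")
        io.write_site_models(world.site_models, out / "site_models.json")
        io.write_catalog(world.catalog, out / "catalog.tsv")
        (out / "truth.json").write_text(json.dumps(world.truth, indent=1, sort_keys=True))

    run_stage("simulate", ["compounds.tsv", "site_models.json", "catalog.tsv", "truth.json"],
              do_simulate)

    # ---- score -------------------------------------------------------
    def do_score(seed):
        compounds = io.read_compounds(out / "compounds.tsv")
        proteins = io.read_site_models(out / "site_models.json")
        matrix = build_matrix(compounds, proteins, protocol=config.protocol)
        io.write_matrix(matrix, out / "matrix.tsv", full_precision=True)

    run_stage("score", ["matrix.tsv"], do_score)

    matrix = io.read_matrix(out / "matrix.tsv")
    catalog = io.read_catalog(out / "catalog.tsv")
    panel = (
        PanelDefinition.full(matrix)
        if config.panel == "human"
        else PanelDefinition("custom", tuple(config.panel))
    )

    # resolve query/candidate ids once, so stage errors name their inputs
    queries = list(config.queries)
    if not queries:
        first_ind = sorted(catalog, key=lambda i: i.indication_id)[0]
        queries = sorted(first_ind.approved_compound_ids)[: config.auto_queries]
    for q in queries:
        if q not in matrix:
            raise StageError("rank", f"unknown query id {q!r}")

    # ---- rank --------------------------------------------------------
    def do_rank(seed):
        frames = []
        for q in queries:
            r = rank_against_query(matrix, q, panel)
            df = r.entries.copy()
            df.insert(0, "query_id", q)
            frames.append(df)
        pd.concat(frames).to_csv(out / "rankings.tsv", sep="\t", index=False)

    run_stage("rank", ["rankings.tsv"], do_rank)

    # ---- aggregate ---------------------------------------------------
    def do_aggregate(seed):
        cands = list(config.candidates)
        if not cands:
            ranks = pd.read_csv(out / "rankings.tsv", sep="\t")
            seen = []
            for q in queries:
                top = ranks.loc[ranks["query_id"] == q].head(config.auto_candidates)
                seen.extend(top["compound_id"].tolist())
            cands = sorted(set(seen))
        for c in cands:
            if c not in matrix:
                raise StageError("aggregate", f"unknown candidate id {c!r}")
        agg = aggregate_multi_query(matrix, queries, cands, panel)
        agg.to_csv(out / "aggregate.csv")
        (out / "aggregate_control.json").write_text(
            json.dumps(agg.attrs["library_mean_control"], indent=1, sort_keys=True)
        )

    run_stage("aggregate", ["aggregate.csv", "aggregate_control.json"], do_aggregate)

    # ---- benchmark ---------------------------------------------------
    def do_benchmark(seed):
        res = benchmark(matrix, catalog, cutoffs=config.cutoffs)
        res.to_frame().to_csv(out / "benchmark_per_indication.csv", index=False)
        n_approved = len(catalog.all_compound_ids() & set(matrix.compound_ids))
        ctrl = random_control(
            catalog, n_approved, cutoffs=config.cutoffs,
            n_reps=config.random_control_reps, seed=seed,
        )
        summary = {
            "average_accuracy": {str(k): res.average[k] for k in res.cutoffs},
            "weighted_average_accuracy": {str(k): res.weighted_average[k] for k in res.cutoffs},
            "n_indications": res.n_indications,
            "random_control_mc": {str(k): ctrl.mc_mean[k] for k in ctrl.cutoffs},
            "random_control_se": {str(k): ctrl.mc_se[k] for k in ctrl.cutoffs},
            "random_control_expected": {str(k): ctrl.expected[k] for k in ctrl.cutoffs},
        }
        (out / "benchmark_summary.json").write_text(json.dumps(summary, indent=1))

    run_stage("benchmark", ["benchmark_per_indication.csv", "benchmark_summary.json"],
              do_benchmark)

    # ---- gi50 --------------------------------------------------------
    v = config.validation
    def do_gi50(seed):
        g = v["gi50"]
        table = generate_dose_response(
            gi50=g["planted_gi50"], hill=g["hill"], top=g["top"], bottom=g["bottom"],
            doses=g["doses"], n_reps=g["n_reps"], noise_sd=g["noise_sd"],
            seed=seed, drug=g["drug"],
        )
        table.to_csv(out / "dose_response.csv", index=False)
        normalize_inhibition(table).to_csv(out / "inhibition.csv", index=False)
        fit = fit_gi50(table, dilution=g["dilution"], drug=g["drug"])
        payload = {
            "drug": g["drug"], "planted_gi50": g["planted_gi50"],
            "gi50": fit.gi50, "hill": fit.hill, "top": fit.top, "bottom": fit.bottom,
            "capped": fit.capped, "rmse": fit.rmse,
        }
        (out / "gi50.json").write_text(json.dumps(payload, indent=1))

    run_stage("gi50", ["dose_response.csv", "inhibition.csv", "gi50.json"], do_gi50)

    # ---- synergy -----------------------------------------------------
    def do_synergy(seed):
        s = v["synergy"]
        table = generate_combination_table(
            s["drug_a"], s["drug_b"], s["params_a"], s["params_b"],
            s["doses_a"], s["doses_b"], bliss_excess=s["bliss_excess"],
            n_reps=s["n_reps"], noise_sd=s["noise_sd"], seed=seed,
        )
        table.to_csv(out / "combination.csv", index=False)
        from drugsig.doseresponse import combination_grid

        combination_grid(table, s["drug_a"], s["drug_b"]).to_csv(
            out / "combination_grid.tsv", sep="\t"
        )
        shifts = combination_potency_shifts(table, s["drug_a"], s["drug_b"])
        shifts.to_csv(out / "synergy_shifts.csv", index=False)
        report = {
            "drug_pair": [s["drug_a"], s["drug_b"]],
            "any_synergy": bool(shifts["synergistic"].any()),
            "max_potency_shift": float(shifts["potency_shift"].max()),
            "single_agent_capped": bool(shifts["single_capped"].any()),
        }
        (out / "synergy.json").write_text(json.dumps(report, indent=1))

    run_stage("synergy", ["combination.csv", "combination_grid.tsv",
                          "synergy_shifts.csv", "synergy.json"], do_synergy)

    # ---- qpcr --------------------------------------------------------
    def do_qpcr(seed):
        q = v["qpcr"]
        table = generate_ct_table(
            q["fold_changes"], noise_sd=q["noise_sd"], n_reps=q["n_reps"],
            seed=seed, reference_condition=q["reference_condition"],
        )
        table.to_csv(out / "ct_table.csv", index=False)
        res = ddct_analysis(table, q["reference_condition"])
        res.to_csv(out / "expression.csv", index=False)

    run_stage("qpcr", ["ct_table.csv", "expression.csv"], do_qpcr)

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
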