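"""End-to-end orchestration: simulate/ingest -> QC -> structure -> BLUE/GCA
-> cross-validation/sweep, with a reproducibility manifest.

The run is configured by a plain YAML/JSON mapping (see RunConfig). Every
stage logs under its own name, records the seed it used, and checksums its
outputs into ``manifest.json``. Re-running with an unchanged configuration
skips stages whose recorded outputs still match their checksums and reloads
their artifacts from disk, so a finished run is idempotent. Any stage
failure aborts the run with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .crossval import ScenarioSpec, run_scenario, sweep_frame, tp_sweep
from .pheno import (
    broad_sense_heritability,
    compute_gca,
    estimate_variance_components,
    fit_blues,
    trait_correlations,
)
from .qc import qc_pipeline
from .sim import SimConfig, simulate_study
from .structure import cluster_labels_series, pcoa, rogers_distance, select_k

logger = logging.getLogger("tcross_gs.pipeline")


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (a SimConfig mapping) or ``inputs``
    (paths: genotypes + trials or blues) must be given.
    """

    out_dir: Path
    seed: int
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=lambda: {"maf_min": 0.05, "max_missing": 0.20})
    structure: dict = field(
        default_factory=lambda: {"axes": 4, "k_min": 2, "k_max": 8, "n_restarts": 50}
    )
    scenarios: list = field(default_factory=lambda: [{"name": "whole_population"}])
    tp_fraction: float = 0.7
    tp_fractions: list | None = None
    rounds: int = 500
    traits: list | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must declare a master seed")
        if "out_dir" not in raw:
            raise ConfigError("config must declare out_dir")
        cfg = cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw["seed"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            qc=raw.get("qc", {"maf_min": 0.05, "max_missing": 0.20}),
            structure=raw.get(
                "structure", {"axes": 4, "k_min": 2, "k_max": 8, "n_restarts": 50}
            ),
            scenarios=raw.get("scenarios", [{"name": "whole_population"}]),
            tp_fraction=float(raw.get("tp_fraction", 0.7)),
            tp_fractions=raw.get("tp_fractions"),
            rounds=int(raw.get("rounds", 500)),
            traits=raw.get("traits"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("give exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            if "genotypes" not in self.inputs:
                raise ConfigError("inputs must name a 'genotypes' path")
            if ("trials" in self.inputs) == ("blues" in self.inputs):
                raise ConfigError("inputs must name exactly one of 'trials' or 'blues'")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input path for {key!r} does not exist: {p}")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "qc": self.qc,
            "structure": self.structure,
            "scenarios": self.scenarios,
            "tp_fraction": self.tp_fraction,
            "tp_fractions": self.tp_fractions,
            "rounds": self.rounds,
            "traits": self.traits,
        }


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, files: list, seed: int | None = None, cached=False):
        self.stages[stage] = {
            "outputs": {str(f): _sha256(f) for f in files},
            "seed": seed,
            "cached": cached,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                fh,
                indent=2,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _cached(prev: dict | None, stage: str) -> bool:
    """A stage is reusable when every recorded output still matches its checksum."""
    if not prev or stage not in prev.get("stages", {}):
        return False
    rec = prev["stages"][stage]
    if not rec["outputs"]:
        return False
    for f, digest in rec["outputs"].items():
        if not Path(f).exists() or _sha256(f) != digest:
            return False
    return True


def run_pipeline(config: RunConfig | dict, force: bool = False) -> RunManifest:
    """Execute all configured stages in order; returns the manifest.

    ``force=True`` recomputes everything, ignoring cached stage outputs.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("tcross_gs")
    root.addHandler(handler)
    if root.level in (logging.NOTSET, logging.WARNING):
        root.setLevel(logging.INFO)

    prev = None
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config") != config.to_dict():
            prev = None  # config changed: recompute everything

    manifest = RunManifest(config=config.to_dict(), version=__version__, seed=config.seed)

    try:
        _run_stages(config, out, prev, manifest)
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest.save(manifest_path)
    return manifest


def _run_stages(config: RunConfig, out: Path, prev, manifest: RunManifest) -> None:
    # stage: data ----------------------------------------------------------
    stage = "data"
    geno_raw = out / "genotypes_raw.tsv"
    trials_csv = out / "trials.csv"
    truth_json = out / "truth.json"
    try:
        if config.simulate is not None:
            if _cached(prev, stage):
                logger.info("[data] cached, reloading")
                panel = tio.read_genotype_table(geno_raw)
                trials = tio.read_trials(trials_csv)
                manifest.record(stage, [geno_raw, trials_csv, truth_json],
                                config.seed, cached=True)
            else:
                sim_cfg = SimConfig(**{"seed": config.seed, **config.simulate})
                logger.info("[data] simulating study (seed=%d)", sim_cfg.seed)
                panel, trials, truth = simulate_study(sim_cfg)
                tio.write_genotype_table(panel, geno_raw)
                tio.write_trials(trials, trials_csv)
                tio.write_json(truth.to_dict(), truth_json)
                manifest.record(stage, [geno_raw, trials_csv, truth_json], sim_cfg.seed)
        else:
            logger.info("[data] loading inputs")
            panel = tio.read_genotype_table(config.inputs["genotypes"])
            trials = (
                tio.read_trials(config.inputs["trials"])
                if "trials" in config.inputs
                else None
            )
            manifest.record(stage, [Path(p) for p in config.inputs.values()], None)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # stage: qc ------------------------------------------------------------
    stage = "qc"
    coded_tsv = out / "genotypes_coded.tsv"
    qc_json = out / "qc_report.json"
    try:
        if _cached(prev, stage):
            logger.info("[qc] cached, reloading")
            genotypes = tio.read_coded_matrix(coded_tsv)
            manifest.record(stage, [coded_tsv, qc_json], cached=True)
        else:
            genotypes, report = qc_pipeline(panel, **config.qc)
            tio.write_genotype_table(genotypes, coded_tsv)
            rep = report.to_dict()
            rep.pop("removed_markers", None)
            tio.write_json(rep, qc_json)
            manifest.record(stage, [coded_tsv, qc_json])
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # stage: structure -----------------------------------------------------
    stage = "structure"
    dist_tsv = out / "rogers_distance.tsv"
    clusters_csv = out / "clusters.csv"
    structure_files = [
        dist_tsv, clusters_csv, out / "pcoa_coordinates.csv", out / "pcoa_eigenvalues.csv"
    ]
    try:
        if _cached(prev, stage):
            logger.info("[structure] cached, reloading")
            labels = tio.read_clusters(clusters_csv)
            manifest.record(stage, structure_files, config.seed, cached=True)
        else:
            st = config.structure
            dist = rogers_distance(genotypes)
            ord_res = pcoa(dist, n_axes=int(st.get("axes", 4)))
            k, sol = select_k(
                ord_res,
                k_range=range(int(st.get("k_min", 2)), int(st.get("k_max", 8)) + 1),
                n_restarts=int(st.get("n_restarts", 50)),
                seed=config.seed,
            )
            labels = cluster_labels_series(sol, genotypes.line_ids)
            tio.write_distance_matrix(dist, dist_tsv)
            tio.write_pcoa(ord_res, out)
            tio.write_clusters(labels, clusters_csv)
            logger.info("[structure] selected k=%d, sizes=%s", k, sol.sizes())
            manifest.record(stage, structure_files, config.seed)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # stage: phenotype -----------------------------------------------------
    stage = "phenotype"
    blues_csv, gca_csv = out / "blues.csv", out / "gca.csv"
    try:
        if _cached(prev, stage):
            logger.info("[phenotype] cached, reloading")
            blues = tio.read_blues(blues_csv)
            gca = tio.read_gca(gca_csv)
            traits = config.traits or sorted(gca["trait"].unique())
            manifest.record(
                stage,
                list(prev["stages"][stage]["outputs"]),
                cached=True,
            )
        else:
            pheno_files = [blues_csv, gca_csv]
            if trials is not None:
                traits = config.traits or sorted(trials["trait"].unique())
                blue_frames, gca_frames, vc_rows = [], [], []
                for trait in traits:
                    blues_t = fit_blues(trials, trait)
                    blue_frames.append(blues_t)
                    gca_frames.append(compute_gca(blues_t, trait))
                    vc = estimate_variance_components(trials, trait)
                    vc_rows.append(
                        {
                            "trait": trait,
                            "sigma2_g": vc.sigma2_g,
                            "sigma2_e": vc.sigma2_e,
                            "n_locations": vc.n_locations,
                            "H2_pct": broad_sense_heritability(vc),
                        }
                    )
                blues = pd.concat(blue_frames, ignore_index=True)
                gca = pd.concat(gca_frames, ignore_index=True)
                vc_csv = out / "variance_components.csv"
                pd.DataFrame(vc_rows).to_csv(vc_csv, index=False)
                pheno_files.append(vc_csv)
            else:
                blues = tio.read_blues_wide(config.inputs["blues"])
                traits = config.traits or sorted(blues["trait"].unique())
                gca = pd.concat(
                    [compute_gca(blues, t) for t in traits], ignore_index=True
                )
            tio.write_blues(blues, blues_csv)
            tio.write_gca(gca, gca_csv)
            if len(traits) >= 2:
                corr_csv = out / "trait_correlations.csv"
                trait_correlations(blues).to_csv(corr_csv)
                pheno_files.append(corr_csv)
            manifest.record(stage, pheno_files)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # stage: cross-validation ----------------------------------------------
    stage = "cv"
    try:
        if _cached(prev, stage):
            logger.info("[cv] cached, skipping")
            manifest.record(stage, list(prev["stages"][stage]["outputs"]),
                            config.seed, cached=True)
        else:
            cv_files = []
            for sc in config.scenarios:
                spec = ScenarioSpec(
                    name=sc.get("name", "whole_population"),
                    cluster=sc.get("cluster"),
                    tp_fraction=float(sc.get("tp_fraction", config.tp_fraction)),
                    n_rounds=int(sc.get("rounds", config.rounds)),
                    seed=int(sc.get("seed", config.seed)),
                )
                for trait in traits:
                    res = run_scenario(spec, gca, genotypes, clusters=labels, trait=trait)
                    tag = f"{spec.name}{'_' + spec.cluster if spec.cluster else ''}_{trait}"
                    rounds_csv = out / f"cv_{tag}_rounds.csv"
                    summary_json = out / f"cv_{tag}.json"
                    tio.write_cv_result(res, rounds_csv, summary_json)
                    cv_files += [rounds_csv, summary_json]
                    logger.info(
                        "[cv] %s %s: mean r_GPA=%.3f se=%.3f",
                        spec.name, trait, res.mean_r_gpa, res.se,
                    )
            if cv_files:
                manifest.record(stage, cv_files, config.seed)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # stage: sweep ---------------------------------------------------------
    stage = "sweep"
    if config.tp_fractions:
        try:
            if _cached(prev, stage):
                logger.info("[sweep] cached, skipping")
                manifest.record(stage, list(prev["stages"][stage]["outputs"]),
                                config.seed, cached=True)
            else:
                sweep_files = []
                for trait in traits:
                    curve = sweep_frame(
                        tp_sweep(
                            gca,
                            genotypes,
                            fractions=config.tp_fractions,
                            n_rounds=config.rounds,
                            seed=config.seed,
                            trait=trait,
                        )
                    )
                    sweep_csv = out / f"sweep_{trait}.csv"
                    curve.to_csv(sweep_csv, index=False)
                    sweep_files.append(sweep_csv)
                manifest.record(stage, sweep_files, config.seed)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
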