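"""Config-driven end-to-end runs with manifests and reproducible seeds.

Stages: simulate -> normalize -> kernels -> hdma -> permute -> h2 ->
translate. Each stage reads its inputs from, and writes its outputs under,
the run directory, so deleting downstream outputs and rerunning reproduces
them bit-identically from upstream files. A run-level manifest records
settings, the seed, and a checksum per written artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .data_io import OmicsMatrix, read_matrix
from .heritability import build_relevance_table, heritability_scan, relevance_heritability_correlation
from .kernels import KernelMatrix, concat_tissues, genome_kernel, linear_kernel
from .mediation import HighDimensionalMediation
from .permutation import permutation_null_path
from .simulate import SimulationConfig, simulate_dataset, simulate_validation_population
from .translate import LocalExpressionImputer, evaluate_prediction, predict_scores

__all__ = ["run_pipeline", "load_config", "ALL_STAGES", "PipelineError"]

ALL_STAGES = ["simulate", "normalize", "kernels", "hdma", "permute", "h2", "translate"]

log = logging.getLogger("hdmediation")


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("config must declare a seed")
    if "simulation" not in cfg and "paths" not in cfg:
        raise ValueError("config needs either a 'simulation' block or input 'paths'")


def _checksum(path: Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: dict, outdir, stages=None) -> dict:
    """Run the requested stages; returns the run manifest dictionary."""
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    artifacts: dict[str, str] = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        func = globals()[f"_stage_{stage}"]
        try:
            written = func(config, outdir)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(stage, str(err)) from err
        for p in written:
            artifacts[str(Path(p).relative_to(outdir))] = _checksum(p)
        log.info("stage %s done in %.2fs (%d artifacts)", stage, time.time() - t0, len(written))
    manifest = {
        "seed": config["seed"],
        "stages": stages,
        "settings": {k: v for k, v in config.items() if k != "paths"},
        "artifacts": artifacts,
    }
    _write_json(outdir / "run_manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------


def _sim_config(config) -> SimulationConfig:
    block = dict(config.get("simulation", {}))
    block.setdefault("seed", config["seed"])
    return SimulationConfig(**block)


def _data_dir(outdir) -> Path:
    return Path(outdir) / "data"


def _load_raw(config, outdir):
    ddir = _data_dir(outdir)
    if config.get("simulation") is not None:
        paths = {
            "dosages": ddir / "genome",
            "expression": {"sim": ddir / "expression.sim.tsv"},
            "phenotypes": ddir / "phenotypes.tsv",
        }
    else:
        paths = config["paths"]
    return data_io.load_dataset(paths)


def _stage_simulate(config, outdir):
    if config.get("simulation") is None:
        return []
    cfg = _sim_config(config)
    dosages, expr, pheno, truth = simulate_dataset(cfg)
    ddir = _data_dir(outdir)
    paths = data_io.write_dataset(ddir, dosages, [expr], pheno)
    truth_path = ddir / "truth.json"
    _write_json(
        truth_path,
        {
            "tss_marker": truth.tss_marker,
            "core_idx": truth.core_idx,
            "core_weights": truth.core_weights,
            "h2_local": truth.h2_local,
            "h2_distal": truth.h2_distal,
            "realized_h2_local": truth.realized_h2_local,
            "realized_h2_distal": truth.realized_h2_distal,
        },
    )
    written = [truth_path, ddir / "genome.dosages.tsv", ddir / "genome.markers.tsv",
               paths["phenotypes"], *paths["expression"].values()]
    return written


def _stage_normalize(config, outdir):
    dosages, tissues, pheno, covariates = _load_raw(config, outdir)
    ndir = Path(outdir) / "normalized"
    ndir.mkdir(exist_ok=True)
    written = []
    norm_tissues = []
    for t in tissues:
        nt = data_io.normalize_features(t)
        if covariates is not None:
            nt = data_io.adjust_covariates(nt, covariates)
        norm_tissues.append(nt)
        p = ndir / f"expression.{t.name}.tsv"
        data_io.write_matrix(nt, p)
        written.append(p)
    npheno = data_io.normalize_features(pheno)
    if covariates is not None:
        npheno = data_io.adjust_covariates(npheno, covariates)
    p = ndir / "phenotypes.tsv"
    data_io.write_matrix(npheno, p)
    written.append(p)
    return written


def _load_normalized(config, outdir):
    ndir = Path(outdir) / "normalized"
    if not ndir.exists():
        raise FileNotFoundError("normalized outputs missing; run the normalize stage first")
    tissues = []
    for p in sorted(ndir.glob("expression.*.tsv")):
        if p.name.endswith(".annotations.tsv"):
            continue
        name = p.name[len("expression."):-len(".tsv")]
        annot = ndir / f"expression.{name}.annotations.tsv"
        tissues.append(read_matrix(p, name=name, annotations_path=annot))
    pheno = read_matrix(ndir / "phenotypes.tsv", name="phenotypes")
    return tissues, pheno


def _stage_kernels(config, outdir):
    dosages, _, _, _ = _load_raw(config, outdir)
    tissues, pheno = _load_normalized(config, outdir)
    kdir = Path(outdir) / "kernels"
    kdir.mkdir(exist_ok=True)
    K_G = genome_kernel(dosages)
    K_T = linear_kernel(concat_tissues(tissues), modality="transcriptome")
    K_P = linear_kernel(pheno, modality="phenome")
    written = []
    for K, name in ((K_G, "genome"), (K_T, "transcriptome"), (K_P, "phenome")):
        p = kdir / f"K_{name}.tsv"
        K.to_frame().to_csv(p, sep="\t", index_label="individual")
        written.append(p)
    return written


def _read_kernel(outdir, name) -> KernelMatrix:
    p = Path(outdir) / "kernels" / f"K_{name}.tsv"
    if not p.exists():
        raise FileNotFoundError(f"kernel {p} missing; run the kernels stage first")
    df = pd.read_csv(p, sep="\t", index_col="individual", float_precision="round_trip")
    df.columns = df.index  # identical id order on both axes
    return KernelMatrix(individual_ids=list(df.index), K=df.to_numpy(), modality=name)


def _stage_hdma(config, outdir):
    tissues, pheno = _load_normalized(config, outdir)
    K_G = _read_kernel(outdir, "genome")
    opts = config.get("hdma", {})
    model = HighDimensionalMediation(
        rank=opts.get("rank"), tol=opts.get("tol", 1e-8),
        max_iter=opts.get("max_iter", 500), random_state=config["seed"],
    )
    model.fit(K_G, tissues, pheno)
    hdir = Path(outdir) / "hdma"
    hdir.mkdir(exist_ok=True)
    scores_p = hdir / "scores.tsv"
    model.scores_.to_csv(scores_p, sep="\t", index_label="individual")
    load_p = hdir / "transcript_loadings.tsv"
    model.transcript_loadings_.table.to_csv(load_p, sep="\t")
    trait_p = hdir / "trait_loadings.tsv"
    model.trait_loadings_.table.to_csv(trait_p, sep="\t")
    fit_p = hdir / "fit.json"
    summary = model.fit_.summary()
    summary["variance_explained"] = model.variance_explained_
    summary["settings"] = {"rank": model.rank, "tol": model.tol, "max_iter": model.max_iter}
    _write_json(fit_p, summary)
    return [scores_p, load_p, trait_p, fit_p]


def _stage_permute(config, outdir):
    tissues, _ = _load_normalized(config, outdir)
    pheno = _load_normalized(config, outdir)[1]
    K_G = _read_kernel(outdir, "genome")
    K_P = linear_kernel(pheno, modality="phenome")
    n_perm = int(config.get("n_perm", 999))
    expr = concat_tissues(tissues)
    opts = config.get("hdma", {})
    result = permutation_null_path(
        K_G, expr, K_P, n_perm=n_perm, seed=int(config["seed"]),
        fit_settings={"rank": opts.get("rank"), "tol": opts.get("tol", 1e-8),
                      "max_iter": opts.get("max_iter", 500)},
    )
    pdir = Path(outdir) / "permutation"
    pdir.mkdir(exist_ok=True)
    json_p = pdir / "permutation.json"
    _write_json(json_p, result.to_dict())
    null_p = pdir / "null_values.tsv"
    pd.Series(result.null_values, name="path_coefficient").to_csv(null_p, sep="\t", index_label="perm")
    return [json_p, null_p]


def _stage_h2(config, outdir):
    dosages, _, _, _ = _load_raw(config, outdir)
    tissues, pheno = _load_normalized(config, outdir)
    opts = config.get("h2", {})
    window = int(opts.get("window_bp", 10_000_000))
    max_t = opts.get("max_transcripts")
    hdir = Path(outdir) / "heritability"
    hdir.mkdir(exist_ok=True)
    written = []
    for t in tissues:
        expr = t
        if max_t is not None and len(expr.feature_ids) > int(max_t):
            keep = expr.feature_ids[: int(max_t)]
            expr = OmicsMatrix(values=expr.values[keep], name=expr.name,
                               feature_annotations=expr.feature_annotations)
        table = heritability_scan(expr, dosages, window_bp=window,
                                  grid_step=float(opts.get("grid_step", 0.01)))
        rel = build_relevance_table(expr, pheno, table)
        p = hdir / f"h2.{t.name}.tsv"
        rel.to_csv(p, sep="\t")
        written.append(p)
        if len(rel) >= 10:  # correlation meaningless on fewer transcripts
            summary = {}
            for comp in ("local", "distal"):
                r, pv = relevance_heritability_correlation(rel, comp)
                summary[f"r_{comp}"] = r
                summary[f"p_{comp}"] = pv
            sp = hdir / f"relevance.{t.name}.json"
            _write_json(sp, summary)
            written.append(sp)
    return written


def _stage_translate(config, outdir):
    if config.get("simulation") is None:
        return []  # translation needs a validation population; simulation-only stage
    cfg = _sim_config(config)
    dosages, expr, pheno, truth = simulate_dataset(cfg)
    val_cfg = SimulationConfig(**{**cfg.__dict__,
                                  **config.get("validation", {"n_individuals": cfg.n_individuals})})
    v_dos, v_expr, v_pheno = simulate_validation_population(truth, val_cfg)
    loadings = pd.read_csv(Path(outdir) / "hdma" / "transcript_loadings.tsv",
                           sep="\t", index_col="feature_id")
    w = loadings["loading"]
    w.index = [i.split(":", 1)[1] if ":" in str(i) else i for i in w.index]
    measured = predict_scores(v_expr, w)
    imputer = LocalExpressionImputer().fit(expr, dosages)
    imputed_expr = imputer.predict(v_dos)
    imputed = predict_scores(imputed_expr, w)
    observed = v_pheno.values.iloc[:, 0]
    rep_measured = evaluate_prediction(measured.scores, observed)
    rep_imputed = evaluate_prediction(imputed.scores, observed)
    tdir = Path(outdir) / "translate"
    tdir.mkdir(exist_ok=True)
    json_p = tdir / "prediction.json"
    _write_json(json_p, {
        "measured": rep_measured.to_dict(),
        "imputed": rep_imputed.to_dict(),
        "n_genes_measured": measured.n_genes,
        "n_genes_imputed": imputed.n_genes,
    })
    tsv_p = tdir / "predicted_scores.tsv"
    pd.DataFrame({"measured": measured.scores, "imputed": imputed.scores,
                  "observed": observed}).to_csv(tsv_p, sep="\t", index_label="individual")
    return [json_p, tsv_p]
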