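"""End-to-end orchestration with provenance.

``run_pipeline`` executes the stages in dependency order —

    data (simulate or load) -> impute -> fit (per-modality nested CV)
    -> stack -> ablate -> reduce -> network

writing every artifact under the configured output directory and recording
a :class:`RunManifest` (config snapshot, package version, per-stage output
digests and wall times).  One global seed fans out to stage-specific
derived seeds (stable hash of stage name + seed), so adding a stage never
perturbs earlier stages' randomness.  With ``resume=True`` a stage whose
recorded input digest matches and whose outputs are intact is reloaded from
disk instead of recomputed, so deleting downstream outputs re-runs only the
downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .crossval import (CVResult, Evaluation, FoldPlan, Fold, HyperGrid,
                       inner_select, make_loso_folds, run_nested_cv)
from .datamodel import (MultiomicsCohort, SampleMetadata, align_cohort,
                        modularity, read_metadata, read_omics_matrix,
                        write_metadata, write_omics_matrix)
from .elastic_net import ElasticNetRegressor, ENHyperparams
from .errors import StageError, ValidationError
from .impute import ImputeConfig, impute_cohort
from .network import FeatureNode, build_mst, layout_network, spearman_matrix
from .reduction import bootstrap_coefficients, threshold_sweep
from .simulate import CohortSpec, ModalitySpec, generate_cohort
from .stacking import ablate, apply_models, stack


def _stage_seed(base: int, stage: str) -> int:
    return (int(base) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one of input paths or a
    simulation spec must be present."""

    outdir: str
    seed: int = 0
    input_matrices: dict | None = None     # modality name -> path
    input_metadata: str | None = None
    simulation: CohortSpec | None = None
    grid: HyperGrid = field(default_factory=lambda: HyperGrid(
        alphas=(0.1, 0.3, 0.5, 0.7, 0.9), n_lambdas=15, lambda_min_ratio=1e-2))
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    bootstrap_iterations: int = 100
    n_thresholds: int = 8
    reduce_modalities: list | None = None   # None = all
    ablation_orders: tuple = ("most_important", "least_important")
    max_network_nodes: int = 250

    def __post_init__(self):
        has_paths = self.input_matrices is not None or self.input_metadata is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValidationError(
                "exactly one of {input paths, simulation spec} must be given"
            )
        if has_paths and (self.input_matrices is None or self.input_metadata is None):
            raise ValidationError(
                "input_matrices and input_metadata must be given together"
            )

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "simulation" in kw and kw["simulation"] is not None:
            sim = dict(kw["simulation"])
            mods = tuple(ModalitySpec(**m) for m in sim.pop("modalities"))
            sim["modalities"] = mods
            kw["simulation"] = CohortSpec(**sim)
        if "grid" in kw and isinstance(kw["grid"], dict):
            g = dict(kw["grid"])
            for key in ("alphas", "fixed_lambdas"):
                if key in g and g[key] is not None:
                    g[key] = tuple(g[key])
            kw["grid"] = HyperGrid(**g)
        if "impute" in kw and isinstance(kw["impute"], dict):
            kw["impute"] = ImputeConfig(**kw["impute"])
        if "ablation_orders" in kw:
            kw["ablation_orders"] = tuple(kw["ablation_orders"])
        return cls(**kw)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)  # name -> record

    def record(self, name: str, inputs_digest: str, outputs: dict,
               wall_seconds: float, info: dict | None = None) -> None:
        self.stages[name] = {
            "inputs_digest": inputs_digest,
            "outputs": outputs,
            "wall_seconds": round(wall_seconds, 3),
            "info": info or {},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], version=d["version"], stages=d["stages"])


# -- CVResult (de)serialization for provenance and resume -------------------

def cvresult_to_dict(res: CVResult) -> dict:
    return {
        "name": res.name,
        "truth": res.truth.to_dict(),
        "blinded_predictions": res.blinded_predictions.to_dict(),
        "training_predictions": res.training_predictions.to_dict(),
        "sample_order": res.truth.index.tolist(),
        "fold_hyperparams": {s: [hp.alpha, hp.lam]
                             for s, hp in res.fold_hyperparams.items()},
        "fold_models": {s: m.to_json_dict() for s, m in res.fold_models.items()},
        "folds": [[f.subject_id, list(f.test_ids), list(f.train_ids)]
                  for f in res.folds],
        "blinded_eval": dataclasses.asdict(res.blinded_eval),
        "training_eval": dataclasses.asdict(res.training_eval),
    }


def cvresult_from_dict(d: dict) -> CVResult:
    order = d["sample_order"]
    return CVResult(
        name=d["name"],
        truth=pd.Series(d["truth"])[order],
        blinded_predictions=pd.Series(d["blinded_predictions"])[order],
        training_predictions=pd.Series(d["training_predictions"])[order],
        fold_hyperparams={s: ENHyperparams(*v)
                          for s, v in d["fold_hyperparams"].items()},
        fold_models={s: ElasticNetRegressor.from_json_dict(m)
                     for s, m in d["fold_models"].items()},
        folds=FoldPlan(tuple(Fold(s, tuple(te), tuple(tr))
                             for s, te, tr in d["folds"])),
        blinded_eval=Evaluation(**d["blinded_eval"]),
        training_eval=Evaluation(**d["training_eval"]),
    )


# ---------------------------------------------------------------------------
# Stage runner
# ---------------------------------------------------------------------------

class _Runner:
    def __init__(self, outdir: Path, manifest: RunManifest,
                 previous: RunManifest | None):
        self.outdir = outdir
        self.manifest = manifest
        self.previous = previous

    def _reusable(self, name: str, inputs_digest: str, outputs: list[Path]) -> bool:
        if self.previous is None or name not in self.previous.stages:
            return False
        rec = self.previous.stages[name]
        if rec["inputs_digest"] != inputs_digest:
            return False
        for path in outputs:
            rel = str(path.relative_to(self.outdir))
            if rel not in rec["outputs"] or not path.exists():
                return False
            if _sha256(path) != rec["outputs"][rel]:
                return False
        return True

    def run(self, name: str, inputs_digest: str, expected_outputs: list[Path],
            compute, reload=None):
        """Execute `compute` (or `reload` when outputs are intact) and record
        the stage.  `compute` must write every expected output."""
        reusable = reload is not None and self._reusable(
            name, inputs_digest, expected_outputs)
        t0 = time.perf_counter()
        try:
            result, info = (reload() if reusable else compute())
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, f"{type(exc).__name__}: {exc}") from exc
        wall = time.perf_counter() - t0
        outputs = {}
        for path in expected_outputs:
            if not path.exists():
                raise StageError(name, f"expected output missing: {path}")
            outputs[str(path.relative_to(self.outdir))] = _sha256(path)
        info = dict(info or {})
        info["reused"] = reusable
        self.manifest.record(name, inputs_digest, outputs, wall, info)
        return result


def _eval_dict(ev: Evaluation) -> dict:
    return {"rho": ev.rho, "p": ev.p, "rmse": ev.rmse,
            "degenerate": ev.degenerate}


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunManifest:
    """Run every stage and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = None
    if resume and manifest_path.exists():
        previous = RunManifest.load(manifest_path)
    manifest = RunManifest(config=config.snapshot(), version=__version__)
    runner = _Runner(outdir, manifest, previous)
    snap = config.snapshot()

    # ---- data ------------------------------------------------------------
    data_dir = outdir / "data"
    data_dir.mkdir(exist_ok=True)

    def data_compute():
        if config.simulation is not None:
            sim = dataclasses.replace(
                config.simulation, seed=_stage_seed(config.seed, "simulate"))
            cohort, truth = generate_cohort(sim)
            gt_path = data_dir / "ground_truth.json"
            with open(gt_path, "w") as fh:
                json.dump({"blocks": truth.blocks}, fh, indent=1)
        else:
            datasets = {
                name: read_omics_matrix(path, name)
                for name, path in sorted(config.input_matrices.items())
            }
            metadata = read_metadata(config.input_metadata)
            cohort = align_cohort(datasets, metadata, mode="intersect")
        write_metadata(cohort.metadata, data_dir / "metadata.csv")
        for name, ds in cohort.datasets.items():
            write_omics_matrix(ds, data_dir / f"{name}.csv")
        return cohort, {"n_samples": len(cohort.metadata),
                        "n_modalities": len(cohort.datasets),
                        "n_instances": cohort.n_instances}

    def data_reload():
        metadata = read_metadata(data_dir / "metadata.csv")
        datasets = {
            p.stem: read_omics_matrix(p, p.stem)
            for p in sorted(data_dir.glob("*.csv")) if p.stem != "metadata"
        }
        cohort = align_cohort(datasets, metadata, mode="strict")
        return cohort, {}

    modality_names = (
        [m.name for m in config.simulation.modalities]
        if config.simulation is not None else sorted(config.input_matrices)
    )
    data_outputs = [data_dir / "metadata.csv"] + [
        data_dir / f"{m}.csv" for m in modality_names]
    if config.simulation is not None:
        data_outputs.append(data_dir / "ground_truth.json")
    data_digest = _digest_obj({"seed": config.seed,
                               "simulation": snap["simulation"],
                               "inputs": snap["input_matrices"],
                               "metadata": snap["input_metadata"]})
    cohort = runner.run("data", data_digest, data_outputs,
                        data_compute, data_reload)

    # ---- impute ----------------------------------------------------------
    imp_dir = outdir / "imputed"
    imp_dir.mkdir(exist_ok=True)
    imp_cfg = ImputeConfig(config.impute.n_trees, config.impute.max_iterations,
                           config.impute.convergence_tol,
                           _stage_seed(config.seed, "impute"))

    def impute_compute():
        completed = impute_cohort(cohort, imp_cfg)
        for name, ds in completed.datasets.items():
            write_omics_matrix(ds, imp_dir / f"{name}.csv")
        mods = {name: int(modularity(ds))
                for name, ds in completed.datasets.items()}
        with open(imp_dir / "modularity.json", "w") as fh:
            json.dump(mods, fh, indent=1)
        return completed, {"modularity": mods}

    def impute_reload():
        datasets = {
            m: read_omics_matrix(imp_dir / f"{m}.csv", m)
            for m in modality_names
        }
        return align_cohort(datasets, cohort.metadata, mode="strict"), {}

    imp_digest = _digest_obj({"upstream": manifest.stages["data"]["outputs"],
                              "impute": snap["impute"], "seed": config.seed})
    imp_outputs = [imp_dir / f"{m}.csv" for m in modality_names]
    imp_outputs.append(imp_dir / "modularity.json")
    completed = runner.run("impute", imp_digest, imp_outputs,
                           impute_compute, impute_reload)

    folds = make_loso_folds(completed.metadata)

    # ---- fit (per-modality nested CV) ------------------------------------
    fit_dir = outdir / "fit"
    fit_dir.mkdir(exist_ok=True)

    def fit_compute():
        results = {}
        for name in modality_names:
            res = run_nested_cv(completed.datasets[name], completed.metadata,
                                config.grid, folds)
            results[name] = res
            with open(fit_dir / f"{name}.json", "w") as fh:
                json.dump(cvresult_to_dict(res), fh)
            pd.DataFrame({
                "truth": res.truth, "blinded_pred": res.blinded_predictions,
                "training_pred": res.training_predictions,
            }).rename_axis("sample_id").to_csv(fit_dir / f"{name}_predictions.csv")
        info = {name: _eval_dict(results[name].blinded_eval)
                for name in modality_names}
        return results, info

    def fit_reload():
        results = {}
        for name in modality_names:
            with open(fit_dir / f"{name}.json") as fh:
                results[name] = cvresult_from_dict(json.load(fh))
        return results, {}

    fit_digest = _digest_obj({"upstream": manifest.stages["impute"]["outputs"],
                              "grid": snap["grid"]})
    fit_outputs = [fit_dir / f"{m}.json" for m in modality_names] + [
        fit_dir / f"{m}_predictions.csv" for m in modality_names]
    base_results = runner.run("fit", fit_digest, fit_outputs,
                              fit_compute, fit_reload)

    # ---- stack -----------------------------------------------------------
    stack_dir = outdir / "stack"
    stack_dir.mkdir(exist_ok=True)

    def stack_compute():
        st = stack(completed, config.grid, folds, base_results=base_results)
        summary = {
            "modalities": st.modality_names,
            "meta_coefficients": st.meta_coefficients.to_dict(),
            "meta_hyperparams": [st.meta_model.alpha, st.meta_model.lam],
            "blinded_eval": _eval_dict(st.meta_cv.blinded_eval),
            "training_eval": _eval_dict(st.meta_cv.training_eval),
        }
        with open(stack_dir / "stacked.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        pd.DataFrame({
            "truth": st.meta_cv.truth,
            "blinded_pred": st.meta_cv.blinded_predictions,
            "training_pred": st.meta_cv.training_predictions,
        }).rename_axis("sample_id").to_csv(stack_dir / "stacked_predictions.csv")
        traj = apply_models(st, completed, target_visits=None)
        traj.to_csv(stack_dir / "trajectories.csv")
        return st, {"blinded_eval": summary["blinded_eval"]}

    stack_digest = _digest_obj({"upstream": manifest.stages["fit"]["outputs"]})
    stack_outputs = [stack_dir / "stacked.json",
                     stack_dir / "stacked_predictions.csv",
                     stack_dir / "trajectories.csv"]
    stacked = runner.run("stack", stack_digest, stack_outputs, stack_compute)

    # ---- ablate ----------------------------------------------------------
    abl_dir = outdir / "ablation"
    abl_dir.mkdir(exist_ok=True)

    def ablate_compute():
        info = {}
        for order in config.ablation_orders:
            trace = ablate(completed, config.grid, folds, order=order,
                           base_results=base_results)
            trace.coefficients_frame().to_csv(
                abl_dir / f"{order}_coefficients.csv", index_label="iteration")
            trace.evaluations().to_csv(
                abl_dir / f"{order}_evaluations.csv", index=False)
            info[order] = trace.removed
        return None, {"removal_order": info}

    abl_digest = _digest_obj({"upstream": manifest.stages["fit"]["outputs"],
                              "orders": list(config.ablation_orders)})
    abl_outputs = []
    for order in config.ablation_orders:
        abl_outputs += [abl_dir / f"{order}_coefficients.csv",
                        abl_dir / f"{order}_evaluations.csv"]
    runner.run("ablate", abl_digest, abl_outputs, ablate_compute)

    # ---- reduce ----------------------------------------------------------
    red_dir = outdir / "reduction"
    red_dir.mkdir(exist_ok=True)
    reduce_mods = config.reduce_modalities or modality_names

    def reduce_compute():
        selected = {}
        profiles = []
        curves = []
        for name in reduce_mods:
            ds = completed.datasets[name]
            hp = inner_select(
                ds.matrix.loc[completed.metadata.pregnancy_sample_ids()],
                completed.metadata.outcome[
                    completed.metadata.pregnancy_sample_ids()],
                completed.metadata.subset(
                    completed.metadata.pregnancy_sample_ids()),
                config.grid)
            profile = bootstrap_coefficients(
                ds, completed.metadata, hp,
                n_iterations=config.bootstrap_iterations,
                seed=_stage_seed(config.seed, f"bootstrap:{name}"))
            curve = threshold_sweep(profile, ds, completed.metadata,
                                    config.grid, folds,
                                    n_thresholds=config.n_thresholds)
            selected[name] = curve.selected_features
            profiles.append(profile.values.rename("mean_abs_coef")
                            .rename_axis("feature_id").reset_index()
                            .assign(modality=name))
            curves.append(curve.table.assign(modality=name))
        pd.concat(profiles).to_csv(red_dir / "profiles.csv", index=False)
        pd.concat(curves).to_csv(red_dir / "curves.csv", index=False)
        with open(red_dir / "selected_features.json", "w") as fh:
            json.dump(selected, fh, indent=1)
        return selected, {"n_selected": {m: len(v) for m, v in selected.items()}}

    def reduce_reload():
        with open(red_dir / "selected_features.json") as fh:
            return json.load(fh), {}

    red_digest = _digest_obj({"upstream": manifest.stages["fit"]["outputs"],
                              "n_iterations": config.bootstrap_iterations,
                              "n_thresholds": config.n_thresholds,
                              "modalities": list(reduce_mods),
                              "seed": config.seed})
    red_outputs = [red_dir / "profiles.csv", red_dir / "curves.csv",
                   red_dir / "selected_features.json"]
    selected = runner.run("reduce", red_digest, red_outputs,
                          reduce_compute, reduce_reload)

    # ---- network ---------------------------------------------------------
    net_dir = outdir / "network"
    net_dir.mkdir(exist_ok=True)

    def network_compute():
        preg = completed.metadata.pregnancy_sample_ids()
        outcome = completed.metadata.outcome[preg].to_numpy(float)
        nodes, columns = [], {}
        for name in reduce_mods:
            feats = selected.get(name) or []
            for f in feats:
                col = completed.datasets[name].matrix.loc[preg, f]
                from .crossval import spearman_test
                r, _, _ = spearman_test(col.to_numpy(float), outcome)
                nodes.append(FeatureNode(name, f, r))
                columns[f"{name}:{f}"] = col.to_numpy(float)
        if len(nodes) > config.max_network_nodes:
            keep = sorted(range(len(nodes)),
                          key=lambda i: -abs(nodes[i].outcome_rho)
                          )[: config.max_network_nodes]
            keep = sorted(keep)
            nodes = [nodes[i] for i in keep]
            columns = {nd.key: columns[nd.key] for nd in nodes}
        feat_df = pd.DataFrame(columns, index=preg)
        rho, p = spearman_matrix(feat_df)
        net = build_mst(nodes, rho, p)
        layout = layout_network(net, seed=_stage_seed(config.seed, "layout"))
        net.edges.to_csv(net_dir / "edges.csv", index=False)
        net.node_table(layout).to_csv(net_dir / "nodes.csv", index=False)
        net.to_graphml(net_dir / "network.graphml")
        return net, {"n_nodes": len(nodes),
                     "n_edges": int(net.edges.shape[0]),
                     "is_tree": bool(net.is_tree)}

    net_digest = _digest_obj({"upstream": manifest.stages["reduce"]["outputs"],
                              "max_nodes": config.max_network_nodes,
                              "seed": config.seed})
    net_outputs = [net_dir / "edges.csv", net_dir / "nodes.csv",
                   net_dir / "network.graphml"]
    runner.run("network", net_digest, net_outputs, network_compute)

    manifest.save(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize_run(manifest: RunManifest, outdir: str | None = None) -> str:
    """Human-readable per-modality and stacked summary of a completed run.

    Reads the stage JSON artifacts referenced by the manifest; missing
    stages are noted rather than fatal.
    """
    outdir = Path(outdir or manifest.config["outdir"])
    lines = [f"omicstack run summary (version {manifest.version})", ""]
    expected = ("data", "impute", "fit", "stack", "ablate", "reduce", "network")
    missing = [s for s in expected if s not in manifest.stages]
    if missing:
        lines.append(f"MISSING STAGES: {', '.join(missing)}")
        lines.append("")

    if "fit" in manifest.stages:
        lines.append(f"{'modality':<20}{'rho':>8}{'p':>12}{'RMSE':>8}")
        for name in sorted(manifest.stages["fit"]["outputs"]):
            if not name.endswith(".json"):
                continue
            with open(outdir / name) as fh:
                d = json.load(fh)
            ev = d["blinded_eval"]
            lines.append(
                f"{d['name']:<20}{ev['rho']:>8.3f}{ev['p']:>12.3g}"
                f"{ev['rmse']:>8.2f}"
            )
    if "stack" in manifest.stages:
        with open(outdir / "stack" / "stacked.json") as fh:
            d = json.load(fh)
        ev = d["blinded_eval"]
        lines.append(f"{'stacked':<20}{ev['rho']:>8.3f}{ev['p']:>12.3g}"
                     f"{ev['rmse']:>8.2f}")
    if "ablate" in manifest.stages:
        info = manifest.stages["ablate"]["info"].get("removal_order", {})
        for order, removed in info.items():
            lines.append(f"ablation ({order}): {' -> '.join(removed)}")
    if "reduce" in manifest.stages:
        info = manifest.stages["reduce"]["info"].get("n_selected", {})
        if info:
            lines.append("selected features: " + ", ".join(
                f"{m}={k}" for m, k in sorted(info.items())))
        else:
            lines.append("reduction ran; see reduction/selected_features.json")
    else:
        lines.append("reduction skipped")
    return "\n".join(lines)
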