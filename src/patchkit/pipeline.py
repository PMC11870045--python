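"""End-to-end orchestration: simulate -> extract -> fit -> cluster -> compare.

A :class:`RunConfig` (parsed from a flat key=value config file with one
section per stage) drives a deterministic run over a synthetic cohort:
every stochastic stage derives its randomness from the single master
seed, so re-running the same config reproduces every output table
byte-for-byte.  Outputs are CSV tables (feature matrix per condition,
Hill-fit table, cluster labels, forest importances, PCA loadings,
paired drug comparisons) plus a JSON run manifest recording the config
hash and seeds.  A stage failure aborts the run and moves any partial
outputs under ``failed/``.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, groupstats, synth
from .features import assemble_features
from .fihill import FitError, HillModel, build_fi
from .io import export_feature_matrix

__all__ = ["RunConfig", "ValidationError", "StageError", "run",
           "extract_cell", "demo_config"]

logger = logging.getLogger("patchkit")

COMPARE_MEASURES = ["max_freq_Hz", "rheobase_pA", "midpoint_pA",
                    "steepness_Hz_per_pA"]


class ValidationError(ValueError):
    """The run configuration is invalid; nothing was computed."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs preserved under failed/."""


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    n_per_type: tuple = (17, 3, 5)
    jitter: float = 0.05
    ca_scale: float = 1.0
    condition: str = "baclofen"
    k: int = 3
    encoding: str = "dummies"
    step_max_pA: float = 200.0
    protocol_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise ValidationError(f"config file not found: {path}")
        if not cp.has_option("run", "seed"):
            raise ValidationError("config must set run.seed explicitly")
        try:
            seed = cp.getint("run", "seed")
        except ValueError as exc:
            raise ValidationError("run.seed must be an integer") from exc
        out_dir = Path(cp.get("run", "out", fallback="patchkit_out"))
        n_per_type = (
            cp.getint("cohort", "n_type1", fallback=17),
            cp.getint("cohort", "n_type2", fallback=3),
            cp.getint("cohort", "n_type3", fallback=5),
        )
        cfg = cls(
            seed=seed,
            out_dir=out_dir,
            n_per_type=n_per_type,
            jitter=cp.getfloat("cohort", "jitter", fallback=0.05),
            ca_scale=cp.getfloat("cohort", "ca_scale", fallback=1.0),
            condition=cp.get("compare", "condition", fallback="baclofen"),
            k=cp.getint("cluster", "k", fallback=3),
            encoding=cp.get("cluster", "encoding", fallback="dummies"),
            step_max_pA=cp.getfloat("protocol", "step_max_pA",
                                    fallback=200.0),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.condition not in synth.CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; choose from "
                f"{sorted(synth.CONDITIONS)}"
            )
        if not 0.0 <= self.ca_scale <= 1.0:
            raise ValidationError("ca_scale must lie in [0, 1]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if any(n < 0 for n in self.n_per_type):
            raise ValidationError("cohort sizes must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), default=str, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def extract_cell(spec: synth.NeuronSpec, condition: str, seed: int,
                 cell_id: str = "cell", step_max_pA: float = 200.0):
    """Simulate the three protocols for one cell and extract features.

    Returns ``(FeatureVector, HillFitResults | None)``.
    """
    protocols = {
        "step": synth.Protocol(kind="step_family", step_max_pA=step_max_pA),
        "test": synth.Protocol(kind="test_pulse", repeats=20),
        "sag": synth.Protocol(kind="sag_pulse", repeats=3),
    }
    sets = {
        name: synth.simulate_sweeps(spec, proto, condition, seed=seed)
        for name, proto in protocols.items()
    }
    from .features import excitability_scalars

    exc = excitability_scalars(sets["step"])
    hill = None
    if not math.isnan(exc.rheobase_pA):
        try:
            hill = HillModel(build_fi(sets["step"], exc.counts)).fit()
        except (FitError, ValueError):
            hill = None
    vec = assemble_features(
        sets["step"], sets["test"], sets["sag"], hill_fit=hill,
        cell_id=cell_id,
    )
    return vec, hill


def _write_csv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, float_format="%.6g", na_rep="NA", **kwargs)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of output paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate+extract"
        cohort = synth.make_cohort(
            config.n_per_type, seed=config.seed, jitter=config.jitter
        )
        conditions = ["control", config.condition]
        vectors: dict[str, list] = {c: [] for c in conditions}
        hill_rows = []
        true_types = {}
        for i, (cell_id, tname, spec) in enumerate(cohort):
            spec = dataclasses.replace(spec, ca_scale=config.ca_scale)
            true_types[cell_id] = tname
            cell_seed = (config.seed * 100003 + i) % (2 ** 31 - 1)
            for cond in conditions:
                logger.info("stage=extract cell=%s condition=%s",
                            cell_id, cond)
                vec, hill = extract_cell(
                    spec, cond, seed=cell_seed, cell_id=cell_id,
                    step_max_pA=config.step_max_pA,
                )
                if vec.excluded:
                    logger.warning(
                        "stage=extract cell=%s condition=%s excluded",
                        cell_id, cond,
                    )
                vectors[cond].append(vec)
                row = {"cell_id": cell_id, "condition": cond,
                       "true_type": tname}
                row.update(hill.params_dict() if hill is not None else {})
                hill_rows.append(row)
        for cond in conditions:
            path = out / f"features_{cond}.csv"
            export_feature_matrix(vectors[cond], path)
            outputs[f"features_{cond}"] = path
        hill_path = out / "hill_fits.csv"
        _write_csv(pd.DataFrame(hill_rows), hill_path, index=False)
        outputs["hill_fits"] = hill_path

        stage = "cluster"
        kept = [v for v in vectors["control"] if not v.excluded]
        matrix = classify.prepare_matrix(kept, encoding=config.encoding)
        cluster = classify.ward_cluster(matrix, k=config.k)
        labels = pd.DataFrame({
            "cell_id": cluster.index,
            "cluster": cluster.labels,
            "true_type": [true_types[c] for c in cluster.index],
        })
        labels_path = out / "cluster_labels.csv"
        _write_csv(labels, labels_path, index=False)
        outputs["cluster_labels"] = labels_path

        report = classify.rf_importance(
            matrix, cluster.labels, seed=config.seed % (2 ** 31 - 1)
        )
        imp = report.importances.rename("importance").to_frame()
        imp.insert(0, "feature", imp.index)
        imp_path = out / "importance.csv"
        _write_csv(imp, imp_path, index=False)
        outputs["importance"] = imp_path

        pca = classify.pca_map(matrix)
        pca_path = out / "pca_loadings.csv"
        _write_csv(pca.loadings, pca_path, index_label="feature")
        outputs["pca_loadings"] = pca_path
        ev_path = out / "pca_explained.csv"
        _write_csv(
            pd.DataFrame({
                "component": [f"PC{i + 1}"
                              for i in range(len(pca.explained_fraction))],
                "explained_fraction": pca.explained_fraction,
            }),
            ev_path, index=False,
        )
        outputs["pca_explained"] = ev_path

        stage = "compare"
        label_of = dict(zip(labels["cell_id"], labels["cluster"]))
        frames = {
            cond: pd.DataFrame([v.as_dict() for v in vectors[cond]])
            .set_index("cell_id")
            for cond in conditions
        }
        comp_rows = []
        for cl in range(1, config.k + 1):
            cells = [c for c, lab in label_of.items() if lab == cl]
            for measure in COMPARE_MEASURES:
                pre = frames["control"].loc[cells, measure].astype(float)
                post = frames[config.condition].loc[cells, measure] \
                    .astype(float)
                ok = pre.notna() & post.notna()
                if ok.sum() < 3:
                    logger.warning(
                        "stage=compare cluster=%d measure=%s skipped "
                        "(n=%d < 3)", cl, measure, int(ok.sum()),
                    )
                    continue
                res = groupstats.paired_compare(pre[ok], post[ok])
                comp_rows.append({
                    "cluster": cl, "measure": measure,
                    "n": res.n, "test": res.test_name,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "mean_control": res.mean_pre, "sd_control": res.sd_pre,
                    f"mean_{config.condition}": res.mean_post,
                    f"sd_{config.condition}": res.sd_post,
                    "percent_change": res.percent_change,
                    "percent_change_rounded": res.percent_change_rounded,
                })
        comp_path = out / "comparisons.csv"
        _write_csv(pd.DataFrame(comp_rows), comp_path, index=False)
        outputs["comparisons"] = comp_path

        stage = "manifest"
        from . import __version__

        manifest = {
            "config": dataclasses.asdict(config),
            "config_sha256": config.config_hash(),
            "seed": config.seed,
            "patchkit_version": __version__,
            "numpy_version": np.__version__,
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, default=str, indent=2,
                                       sort_keys=True) + "\n")
        outputs["manifest"] = man_path
    except ValidationError:
        raise
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for path in outputs.values():
            if path.exists():
                shutil.move(str(path), failed / path.name)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return outputs


def demo_config(out_dir, seed: int = 1) -> RunConfig:
    """The demo scenario: 25 synthetic cells (17/3/5 per type), control
    vs baclofen at high extracellular Ca (ca_scale = 1)."""
    return RunConfig(
        seed=seed, out_dir=Path(out_dir), n_per_type=(17, 3, 5),
        condition="baclofen", ca_scale=1.0,
    )
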