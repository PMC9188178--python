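"""End-to-end experiment orchestration from a declarative config."""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classifiers import EvalReport, evaluate_model, train_classifier
from .segmentation import SpectrumTable
from .simulate import ScenarioConfig, confusable_scenario, simulate_scenario
from .spa import SPAResult, spa_select
from .update import UpdateLog, VerificationSet, active_update, verify_external

__all__ = ["ExperimentConfig", "run_experiment"]

_SOURCES = ("scenario", "spectra_csv", "feature_csv")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    Exactly one input source must be set: a simulator ``scenario`` dict,
    a ``spectra_csv`` path, or a ``feature_csv`` path.
    """

    scenario: dict | None = None
    spectra_csv: str | None = None
    feature_csv: str | None = None
    surface_mode: str = "mixed"  # germ | non-germ | mixed
    feature_mode: str = "full-spectrum"  # full-spectrum | spa | rgb-54
    algorithm: str = "svm"
    runs: int = 10
    seed: int = 0
    model_config: dict = field(default_factory=dict)
    spa_config: dict = field(default_factory=dict)
    update: dict | None = None
    outdir: str | None = None

    def validate(self) -> None:
        sources = [s for s in _SOURCES if getattr(self, s) is not None]
        if len(sources) != 1:
            raise ValueError(
                f"exactly one input source required, got {sources or 'none'}"
            )
        if self.surface_mode not in ("germ", "non-germ", "mixed"):
            raise ValueError(f"unknown surface_mode {self.surface_mode!r}")
        if self.feature_mode not in ("full-spectrum", "spa", "rgb-54"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        for s in ("spectra_csv", "feature_csv"):
            p = getattr(self, s)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @staticmethod
    def from_dict(raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return ExperimentConfig(**raw)


def _load_table(cfg: ExperimentConfig) -> SpectrumTable:
    if cfg.scenario is not None:
        scen = ScenarioConfig(**{**cfg.scenario, "seed": cfg.scenario.get("seed", cfg.seed)})
        return simulate_scenario(scen)
    if cfg.spectra_csv is not None:
        return SpectrumTable.from_csv(cfg.spectra_csv)
    raise ValueError("feature_csv input is handled separately")


def _filter_surface(table: SpectrumTable, mode: str) -> SpectrumTable:
    if mode == "mixed":
        return table
    keep = table.meta["surface"].to_numpy() == mode
    if not keep.any():
        raise ValueError(f"no rows with surface {mode!r}")
    return table.select(keep)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute extract -> (optional SPA) -> train -> evaluate -> (optional update).

    Returns a results bundle; when ``cfg.outdir`` is set, a manifest and
    the serializable artifacts are written there.
    """
    cfg.validate()
    bundle: dict = {"config": dataclasses.asdict(cfg)}

    if cfg.feature_csv is not None:
        import pandas as pd

        from .features import FEATURE_NAMES

        df = pd.read_csv(cfg.feature_csv)
        X = df[FEATURE_NAMES].to_numpy(dtype=float)
        y = (df["category"].to_numpy() == "target").astype(int)
        strata = df["category"].to_numpy()
        schema = list(FEATURE_NAMES)
        wavelengths = None
    else:
        table = _filter_surface(_load_table(cfg), cfg.surface_mode)
        X = table.spectra
        y = table.y
        strata = table.meta["category"].to_numpy()
        wavelengths = table.wavelengths
        schema = [f"wl_{w:g}" for w in wavelengths]

    spa_result: SPAResult | None = None
    if cfg.feature_mode == "spa":
        if wavelengths is None:
            raise ValueError("feature_mode='spa' requires spectral input")
        from .classifiers import split_dataset

        split = split_dataset(strata, seed=cfg.seed)
        spa_result = spa_select(
            X[split.train_idx],
            y[split.train_idx],
            X[split.test_idx],
            y[split.test_idx],
            wavelengths=wavelengths,
            **cfg.spa_config,
        )
        X = X[:, spa_result.selected]
        schema = [schema[i] for i in spa_result.selected]
        bundle["spa"] = spa_result.to_dict()

    report: EvalReport = evaluate_model(
        cfg.algorithm,
        X,
        y,
        strata=strata,
        runs=cfg.runs,
        seed=cfg.seed,
        config=dict(cfg.model_config),
        schema=schema,
    )
    bundle["evaluation"] = report.to_dict()

    model = train_classifier(
        cfg.algorithm, X, y, config=dict(cfg.model_config), seed=cfg.seed, schema=schema
    )
    bundle["model_metadata"] = model.metadata

    if cfg.update is not None:
        upd = dict(cfg.update)
        ext_seed = upd.pop("scenario_seed", cfg.seed)
        # external set from the confusable reference scenario unless a CSV is given
        ext_csv = upd.pop("external_csv", None)
        if ext_csv is not None:
            ext_table = SpectrumTable.from_csv(ext_csv)
        else:
            _, ext_table = confusable_scenario(seed=ext_seed)
        if cfg.feature_mode == "spa" and spa_result is not None:
            ext_table = ext_table.select_bands(spa_result.selected)
        vset = VerificationSet.from_spectrum_table(ext_table)
        accs, avg = verify_external(model, vset)
        bundle["verification"] = {"per_variety": accs, "average": avg}
        model, log = active_update(
            cfg.algorithm,
            X,
            y,
            vset,
            seed=cfg.seed,
            config=dict(cfg.model_config),
            schema=schema,
            **upd,
        )
        bundle["update_log"] = log.to_dict()

    if cfg.outdir is not None:
        _write_bundle(bundle, Path(cfg.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    import time

    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    for key in ("evaluation", "spa", "update_log", "verification"):
        if key in bundle:
            path = outdir / f"{key}.json"
            path.write_text(json.dumps(bundle[key], indent=2, default=str))
            artifacts[key] = str(path)
    manifest = {
        "config": bundle["config"],
        "seed": bundle["config"]["seed"],
        "versions": {
            "seedscreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "artifacts": artifacts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest_path"] = str(outdir / "manifest.json")
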