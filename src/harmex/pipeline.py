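"""End-to-end orchestration: configuration, staged runs, and artifact manifests.

A run executes pre-modeling statistics, model fitting, and held-out model
comparison (optionally a recovery study) over an input ratings CSV or a
freshly simulated dataset, writing plain CSV/JSON artifacts plus a manifest
listing every output with its SHA-256 hash; runs are reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import premodel
from .chords import RatingDataset, read_dor_csv, write_dor_csv
from .evaluation import SplitScheme, model_comparison
from .fitting import coordinate_descent_fit
from .models import Model, key_profile, params_to_json
from .simulate import recovery_study, sample_params, simulate_experiment

__all__ = ["RunConfig", "PRESETS", "run_pipeline"]

log = logging.getLogger("harmex")

ALL_MODELS = ("1P", "2P", "1M", "2M", "BU", "BS")

#: Scale presets: 'paper' mirrors the original estimation budget, 'ci' keeps a
#: full pipeline run at desk scale.
PRESETS = {
    "paper": {"restarts": 100, "repetitions": 100, "models": ALL_MODELS},
    "ci": {"restarts": 3, "repetitions": 3, "models": ("1P", "1M", "BU")},
}


@dataclass
class RunConfig:
    outdir: str
    input: str | None = None
    preset: str = "ci"
    models: tuple[str, ...] | None = None
    scheme: str = "kfold"
    k: int = 10
    restarts: int | None = None
    repetitions: int | None = None
    seed: int = 0
    simulate_model: str = "BU"
    participants: int = 5
    noise_sd: float = 1.0
    mode: str = "discrete"
    run_recovery: bool = False

    def resolved(self) -> "RunConfig":
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        p = PRESETS[self.preset]
        out = RunConfig(**{**asdict(self), "models": tuple(self.models or p["models"])})
        if out.restarts is None:
            out.restarts = p["restarts"]
        if out.repetitions is None:
            out.repetitions = p["repetitions"]
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    doc = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute premodel -> fit -> evaluate (-> recovery) and write a manifest."""
    config = config.resolved()
    if config.input is not None and not Path(config.input).exists():
        raise FileNotFoundError(f"input path does not exist: {config.input}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    rng = np.random.default_rng(config.seed)

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path)
        files.append(path)

    def save_text(text: str, name: str) -> None:
        path = outdir / name
        path.write_text(text)
        files.append(path)

    # --- input stage -----------------------------------------------------
    if config.input is not None:
        log.info("loading ratings from %s", config.input)
        dataset = read_dor_csv(config.input)
    else:
        log.info("simulating dataset from a planted %s model", config.simulate_model)
        planted = sample_params(Model(config.simulate_model), rng=rng)
        dataset = simulate_experiment(
            planted,
            participants=config.participants,
            mode=config.mode,
            noise_sd=config.noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        save_text(params_to_json(planted), "planted_params.json")
        path = outdir / "dataset.csv"
        write_dor_csv(dataset, path)
        files.append(path)

    # --- premodel stage ---------------------------------------------------
    log.info("premodel: factor tests and grouping analyses")
    tests = []
    mean2 = premodel.average_dors(dataset, 2)
    save_df(mean2.to_frame(), "mean_dor_2chord.csv")
    for factor in ("interval", "first_pitch", "second_pitch"):
        tests.append(premodel.kruskal_wallis_by_factor(mean2, factor))
    mean3 = premodel.average_dors(dataset, 3)
    save_df(mean3.to_frame(), "mean_dor_3chord.csv")
    for treatment in ("interval_from_first", "interval_from_second"):
        tests.append(premodel.friedman_by_interval(mean3, treatment))
    gain, gain_test, posthoc = premodel.context_gain_analysis(dataset)
    tests.append(gain_test)
    save_df(gain, "context_gain.csv")
    save_df(posthoc, "context_gain_posthoc.csv")
    save_df(pd.DataFrame([asdict(t) for t in tests]), "premodel_tests.csv")

    vectors = premodel.interval_profile_vectors(dataset)
    prof_df = pd.DataFrame(
        [v.values for v in vectors],
        index=[v.label for v in vectors],
        columns=list(vectors[0].intervals),
    )
    save_df(prof_df, "interval_profiles.csv")
    D = premodel.profile_distance_matrix(vectors)
    coords, stress = premodel.nonmetric_mds(D, dims=2, seed=config.seed)
    mds_df = pd.DataFrame(coords, index=[v.label for v in vectors], columns=["dim1", "dim2"])
    mds_df["stress"] = stress
    save_df(mds_df, "mds_embedding.csv")
    dend = premodel.complete_link_clustering(D)
    save_df(
        pd.DataFrame(dend.merges, columns=["left", "right", "height", "size"]),
        "dendrogram.csv",
    )

    # --- fitting stage ----------------------------------------------------
    fit_seeds = rng.integers(0, 2**31 - 1, size=len(config.models))
    costs = []
    for model_name, fseed in zip(config.models, fit_seeds):
        log.info("fit: model %s (%d restarts)", model_name, config.restarts)
        fit = coordinate_descent_fit(
            dataset, Model(model_name), restarts=config.restarts, seed=int(fseed)
        )
        save_text(params_to_json(fit.params), f"params_{model_name}.json")
        costs.append({"model": model_name, "train_cost": fit.cost, "n_trials": fit.n_trials})
        if model_name in ("BU", "BS"):
            profile = key_profile(fit.params.T, dor_scale=True)
            save_df(
                pd.DataFrame({"interval_from_reference": range(12), "ideal_dor": profile}),
                f"key_profile_{model_name}.csv",
            )
    save_df(pd.DataFrame(costs), "fit_costs.csv")

    # --- evaluation stage ---------------------------------------------------
    log.info("evaluate: %s scheme over %s", config.scheme, ", ".join(config.models))
    scheme = SplitScheme(config.scheme, k=config.k, seed=config.seed)
    comparison = model_comparison(
        dataset, list(config.models), scheme, restarts=config.restarts,
        seed=int(rng.integers(2**31 - 1)),
    )
    save_df(comparison.table, "model_comparison.csv")
    entropies = {
        "units": comparison.units,
        "train": {m: list(v) for m, v in comparison.train_entropies.items()},
        "test": {m: list(v) for m, v in comparison.test_entropies.items()},
    }
    save_text(json.dumps(entropies, indent=1), "entropies.json")

    # --- recovery stage (optional) -----------------------------------------
    if config.run_recovery:
        rows = []
        for model_name in config.models:
            log.info("recovery: model %s (%d repetitions)", model_name, config.repetitions)
            rep = recovery_study(
                Model(model_name),
                repetitions=config.repetitions,
                restarts=config.restarts,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "model": model_name,
                    "repetitions": rep.repetitions,
                    "max_abs_bias": rep.max_abs_bias,
                    "max_sd": rep.max_sd,
                }
            )
        save_df(pd.DataFrame(rows), "recovery_summary.csv")

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "files": {p.name: _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
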