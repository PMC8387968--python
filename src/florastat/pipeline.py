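"""Run configuration, orchestration and report assembly.

One :class:`RunConfig` drives a full reproducible analysis: load (or
simulate) the observation table, classify, run the iterated subsampling per
setting, the paired setting comparison, the grouped cross-table analyses,
the frequency null model, the image-characteristics GLMM and the training
image associations.  Every stage writes a CSV into the output directory and
the run ends with a JSON manifest plus a human-readable summary.  Identical
config and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (group_training_comparison, species_success,
                          training_correlation)
from .contingency import grouped_class_analysis
from .data_model import TaxonomyMap, classify_table, load_observations
from .errors import ConfigurationError, FlorastatError, ValidationError
from .glmm import estimated_marginal_means, fit_binary_mixed, type3_wald
from .resampling import compare_settings, frequency_null_test, iterate_subsample
from .synthetic import SimulationConfig, generate_observations, generate_species_table

logger = logging.getLogger("florastat")

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "simulation_config_from_dict"]

GROUPINGS = ("family", "growth_form", "life_form", "habitat")

_CONFIG_DEFAULTS: dict = {
    "observations": None,       # CSV path (ignored when simulate is given)
    "species": None,            # CSV path
    "synonyms": None,           # optional synonym CSV path
    "simulate": None,           # SimulationConfig mapping
    "n_iterations": 1000,
    "alpha": 0.05,
    "flag_lower": 0.05,
    "flag_upper": 0.95,
    "min_group_size": 10,       # family grouping; other traits use >= 2
    "min_obs_glmm": 3,
    "fisher_B": 2000,
    "n_rand": 1000,
    "exact_cap": 500,
    "seed": 0,
    "output_dir": "florastat_out",
}


@dataclass
class RunConfig:
    observations: str | None = None
    species: str | None = None
    synonyms: str | None = None
    simulate: dict | None = None
    n_iterations: int = 1000
    alpha: float = 0.05
    flag_lower: float = 0.05
    flag_upper: float = 0.95
    min_group_size: int = 10
    min_obs_glmm: int = 3
    fisher_B: int = 2000
    n_rand: int = 1000
    exact_cap: int = 500
    seed: int = 0
    output_dir: str = "florastat_out"

    def validate(self) -> "RunConfig":
        if self.simulate is None and (self.observations is None
                                      or self.species is None):
            raise ConfigurationError(
                "either a simulate block or observations+species paths required")
        for name in ("n_iterations", "min_group_size", "min_obs_glmm",
                     "fisher_B", "n_rand"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.flag_lower < self.flag_upper < 1.0:
            raise ConfigurationError("flag thresholds must satisfy "
                                     "0 < lower < upper < 1")
        if abs(self.flag_lower - (1.0 - self.flag_upper)) > 1e-12:
            raise ConfigurationError(
                "flag thresholds must be symmetric: lower = 1 - upper")
        return self


def simulation_config_from_dict(block: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - known
    if unknown:
        raise ConfigurationError(f"unknown simulate keys: {sorted(unknown)}")
    block = dict(block)
    if "replicate_range" in block:
        block["replicate_range"] = {
            k: tuple(v) for k, v in block["replicate_range"].items()}
    return SimulationConfig(**block).validate()


def validate_config(source) -> RunConfig:
    """Normalize a YAML/JSON file path or a mapping into a RunConfig.

    Unknown keys raise (no silent ignoring); defaults are filled for
    anything absent.  Normalization is idempotent.
    """
    if isinstance(source, RunConfig):
        return source.validate()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **raw}
    for name in ("n_iterations", "min_group_size", "min_obs_glmm",
                 "fisher_B", "n_rand", "exact_cap", "seed"):
        if not isinstance(merged[name], int) or isinstance(merged[name], bool):
            raise ConfigurationError(f"config key {name!r} must be an integer")
    for name in ("alpha", "flag_lower", "flag_upper"):
        if not isinstance(merged[name], (int, float)):
            raise ConfigurationError(f"config key {name!r} must be numeric")
        merged[name] = float(merged[name])
    cfg = RunConfig(**merged)
    if cfg.simulate is not None:
        simulation_config_from_dict({**cfg.simulate, "seed":
                                     cfg.simulate.get("seed", cfg.seed)})
    return cfg.validate()


# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config) -> dict:
    """Execute the full analysis; returns the run manifest.

    ``config`` is a RunConfig, a mapping or a config file path.  Any stage
    failure aborts with the stage name; the manifest on disk then marks the
    bundle as incomplete.
    """
    cfg = validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "florastat_version": __version__,
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "status": "incomplete",
        "outputs": [],
        "notes": [],
    }
    stage = "setup"

    def emit(name: str, df: pd.DataFrame) -> None:
        _write_csv(df, out / name)
        manifest["outputs"].append(name)

    try:
        # ---- load or simulate -----------------------------------------
        stage = "load"
        if cfg.simulate is not None:
            sim = simulation_config_from_dict(
                {**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
            species = generate_species_table(sim)
            obs, truth = generate_observations(species, sim)
            taxonomy = TaxonomyMap.from_species_table(species)
            _write_csv(obs, out / "observations.csv")
            _write_csv(species, out / "species.csv")
            truth.to_json(out / "simulation_truth.json")
            manifest["outputs"] += ["observations.csv", "species.csv",
                                    "simulation_truth.json"]
        else:
            synonyms = None
            if cfg.synonyms:
                syndf = pd.read_csv(cfg.synonyms, dtype=str)
                synonyms = dict(zip(syndf["synonym"], syndf["accepted"]))
            obs, species = load_observations(cfg.observations, cfg.species)
            taxonomy = TaxonomyMap.from_species_table(species, synonyms)
        manifest["n_observations"] = int(len(obs))
        manifest["n_species"] = int(species["accepted_name"].nunique())

        stage = "classify"
        obs = classify_table(obs, taxonomy)
        emit("classified_observations.csv", obs)

        # ---- iterated subsampling per setting -------------------------
        stage = "subsample"
        pct_rows = []
        streams = {}
        for setting in ("database", "field"):
            sub = obs[obs["setting"] == setting]
            if sub.empty:
                manifest["notes"].append(f"no observations in setting {setting}")
                continue
            summary, stream = iterate_subsample(
                sub, cfg.n_iterations, cfg.seed, stream_name=f"subsample_{setting}")
            streams[setting] = stream
            frame = summary.to_frame()
            frame.insert(0, "setting", setting)
            for lvl, v in summary.cumulative.items():
                frame = pd.concat([frame, pd.DataFrame([{
                    "setting": setting, "id_class": lvl,
                    "mean_percent": v, "mc_se": float("nan")}])],
                    ignore_index=True)
            pct_rows.append(frame)
        emit("class_percentages.csv", pd.concat(pct_rows, ignore_index=True))

        # ---- paired database/field comparison -------------------------
        stage = "paired_comparison"
        db = obs[obs["setting"] == "database"]
        fd = obs[obs["setting"] == "field"]
        if len(db) and len(fd):
            try:
                paired = compare_settings(db, fd, cfg.n_iterations, cfg.seed,
                                          alpha=cfg.alpha)
                frame = paired.to_frame()
                frame.insert(0, "n_common_species", paired.n_common_species)
                emit("paired_comparison.csv", frame)
            except ValidationError as exc:
                manifest["notes"].append(f"paired comparison skipped: {exc}")
        else:
            manifest["notes"].append("paired comparison skipped: one setting only")

        # ---- merged stream for grouped + frequency analyses -----------
        stage = "merged_subsample"
        merged_summary, merged_stream = iterate_subsample(
            obs, cfg.n_iterations, cfg.seed, stream_name="subsample_merged")
        frame = merged_summary.to_frame()
        frame.insert(0, "setting", "merged")
        emit("class_percentages_merged.csv", frame)

        stage = "grouped_analysis"
        fisher_rows = []
        for grouping in GROUPINGS:
            min_size = cfg.min_group_size if grouping == "family" else 2
            try:
                res = grouped_class_analysis(
                    merged_stream, species, grouping,
                    min_group_size=min_size, fisher_B=cfg.fisher_B,
                    n_rand=cfg.n_rand, seed=cfg.seed,
                    exact_cap=cfg.exact_cap)
            except ValidationError as exc:
                manifest["notes"].append(f"grouping {grouping} skipped: {exc}")
                continue
            cells = res.cells_frame()
            pct_long = res.percentages.reset_index().melt(
                id_vars="group", var_name="id_class", value_name="percent")
            cells = cells.merge(pct_long, on=["group", "id_class"])
            emit(f"grouped_{grouping}.csv", cells)
            fisher_rows.append({"grouping": grouping,
                                "median_p": res.fisher.median_p,
                                "max_p": res.fisher.max_p})
        emit("fisher_summary.csv", pd.DataFrame(fisher_rows))

        stage = "frequency_null"
        freq = frequency_null_test(merged_stream, species, seed=cfg.seed)
        emit("frequency_null.csv", freq.to_frame())

        # ---- GLMM of image characteristics ----------------------------
        stage = "glmm"
        try:
            fit = fit_binary_mixed(obs, min_obs=cfg.min_obs_glmm)
            wald = type3_wald(fit)
            emit("glmm_wald.csv", wald)
            emm_frames = [estimated_marginal_means(fit, f, alpha=cfg.alpha
                                                   ).to_frame()
                          for f in fit.factor_levels]
            emit("glmm_emmeans.csv", pd.concat(emm_frames, ignore_index=True))
            manifest["glmm"] = {
                "n_obs_used": fit.n_obs_used,
                "n_species_used": fit.n_species_used,
                "sigma_species": fit.sigma_u,
                "converged": fit.converged,
                "reference_levels": fit.reference,
            }
        except ValidationError as exc:
            manifest["notes"].append(f"glmm skipped: {exc}")

        # ---- training-image associations ------------------------------
        stage = "association"
        succ = species_success(obs)
        emit("species_success.csv", succ)
        corr = training_correlation(succ, species)
        emit("training_correlation.csv", corr.to_frame())
        gt_rows, gt_means = [], []
        for grouping in GROUPINGS:
            try:
                res = group_training_comparison(species, grouping,
                                                alpha=cfg.alpha)
            except ValidationError as exc:
                manifest["notes"].append(
                    f"training comparison {grouping} skipped: {exc}")
                continue
            gt_rows.append(res.anova_frame())
            means = res.means.copy()
            means.insert(0, "grouping", grouping)
            gt_means.append(means)
        if gt_rows:
            emit("group_training.csv", pd.concat(gt_rows, ignore_index=True))
            emit("group_training_means.csv",
                 pd.concat(gt_means, ignore_index=True))

        manifest["status"] = "complete"
    except FlorastatError:
        manifest["notes"].append(f"failed during stage {stage!r}")
        _write_manifest(manifest, out)
        raise
    except Exception as exc:
        manifest["notes"].append(f"failed during stage {stage!r}")
        _write_manifest(manifest, out)
        raise FlorastatError(f"stage {stage!r} failed: {exc}") from exc

    _write_manifest(manifest, out)
    _write_summary(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_summary(manifest: dict, out: Path) -> None:
    lines = [
        "florastat run summary",
        "=====================",
        f"status: {manifest['status']}",
        f"seed: {manifest['seed']}",
        f"observations: {manifest.get('n_observations', 'n/a')}",
        f"species: {manifest.get('n_species', 'n/a')}",
        "outputs:",
    ]
    lines += [f"  - {name}" for name in manifest["outputs"]]
    if manifest["notes"]:
        lines.append("notes:")
        lines += [f"  - {n}" for n in manifest["notes"]]
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
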