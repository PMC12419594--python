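"""End-to-end orchestration: data -> screening -> per-species models ->
richness -> conservation priorities.

Every stage writes plain CSV (plus a JSON manifest) into a run directory,
and a rerun with the same configuration and seed reproduces the outputs
byte for byte.  Stages communicate only through these declared files and the
in-memory :class:`RunResult`; each can be invoked on its own from the CLI,
in which case upstream stages are recomputed (they are cheap and
deterministic, so recomputation is simpler and safer than resuming from
partial state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import background as bg
from . import data as dm
from . import evaluation as ev
from . import maxent as mx
from . import prioritize as pr
from . import synthetic as syn
from .errors import DataError, InvalidConfigError

STAGES = ("simulate", "screen", "background", "fit", "evaluate", "richness", "prioritize")


@dataclass
class PipelineConfig:
    """All pipeline settings; the defaults are the study's stated values.

    ``input_dir`` points at catchments.csv / covariates.csv /
    priority_covariates.csv / occurrences.csv / surveys.csv (+ optional
    species.csv with RSGCN ranks).  When it is None a synthetic landscape is
    generated instead, governed by ``landscape``/``survey``/``seed``.
    """

    input_dir: str | None = None
    landscape: syn.LandscapeConfig | None = None
    survey: syn.SurveyModel | None = None
    cutoff_year_model: int = 1952
    cutoff_year_survey_binary: int = 1992
    correlation_threshold: float = 0.70
    vif_limit: float = 5.0
    keep_priority: list[str] | None = None
    n_background: int = 10_000
    weight_mode: str = "catchment_share"
    background_floor_frac: float = 0.1
    beta_grid: list[float] = field(default_factory=lambda: list(range(1, 16)))
    feature_classes: tuple[str, ...] = mx.ALL_CLASSES
    n_knots: int = 10
    output_transform: str = "logistic"
    cbi_n_windows: int = 101
    cbi_window_width: float = 0.1
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beta_grid:
            raise InvalidConfigError("beta_grid must be nonempty")
        if self.output_transform not in mx.TRANSFORMS:
            raise InvalidConfigError(f"unknown output transform {self.output_transform!r}")
        if self.k_folds < 2:
            raise InvalidConfigError("k_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "landscape" in raw and raw["landscape"] is not None:
            raw["landscape"] = syn.LandscapeConfig(**raw["landscape"])
        if "survey" in raw and raw["survey"] is not None:
            sv = dict(raw["survey"])
            if "year_range" in sv:
                sv["year_range"] = tuple(sv["year_range"])
            raw["survey"] = syn.SurveyModel(**sv)
        if "feature_classes" in raw:
            raw["feature_classes"] = tuple(raw["feature_classes"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        return out


def _derive_seed(seed: int, *keys: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


@dataclass
class SpeciesResult:
    species_id: str
    model: mx.SpeciesModel
    tuning: mx.TuningResult
    predictions: pd.Series
    report: ev.EvaluationReport
    binary: pd.Series
    background_ids: list
    kfold_sd: pd.Series | None = None


@dataclass
class RunResult:
    config: PipelineConfig
    frame: dm.CatchmentFrame
    covariates: dm.CovariateTable
    screening: dm.ScreeningReport
    presences: dict[str, set]
    rsgcn_ranks: dict[str, str]
    species: dict[str, SpeciesResult]
    richness: pd.DataFrame | None = None
    survey_surface: pd.Series | None = None
    protection_surface: pd.Series | None = None
    restoration_surfaces: dict[str, pd.Series] = field(default_factory=dict)
    interspecies_rho: pd.DataFrame | None = None
    protection_vs_protected: dict[str, float] | None = None
    state_summary: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    dataset: syn.SyntheticDataset | None = None


def load_inputs(input_dir: str):
    """Read the five input CSVs (+ optional species.csv)."""
    d = Path(input_dir)
    frame = dm.CatchmentFrame.from_csv(d / "catchments.csv")
    covariates = dm.CovariateTable(pd.read_csv(d / "covariates.csv"))
    aux = pd.read_csv(d / "priority_covariates.csv")
    surveys = pd.read_csv(d / "surveys.csv")
    occurrences = pd.read_csv(d / "occurrences.csv")
    ranks: dict[str, str] = {}
    sp_path = d / "species.csv"
    if sp_path.exists():
        sp = pd.read_csv(sp_path)
        ranks = dict(zip(sp["species_id"], sp["rsgcn_rank"]))
    return frame, covariates, aux, surveys, occurrences, ranks


def run_pipeline(
    config: PipelineConfig,
    outdir: str | None = None,
    stop_after: str = "prioritize",
) -> RunResult:
    """Execute the pipeline through ``stop_after`` and write outputs.

    Species are processed one at a time in sorted id order.  A stage failure
    raises with the stage and species named; outputs written so far remain on
    disk.
    """
    if stop_after not in STAGES:
        raise InvalidConfigError(f"unknown stage {stop_after!r}")
    stop_idx = STAGES.index(stop_after)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # ---- stage: simulate / load -------------------------------------------
    dataset = None
    if config.input_dir is not None:
        frame, covariates, aux, surveys_all, occurrences_all, ranks = load_inputs(
            config.input_dir
        )
    else:
        dataset = syn.simulate_dataset(
            landscape=config.landscape,
            survey_model=config.survey,
            seed=config.seed,
        )
        frame = dm.CatchmentFrame(dataset.catchments)
        covariates = dm.CovariateTable(dataset.covariates, dataset.covariate_kinds)
        aux = dataset.priority_covariates
        surveys_all = dataset.surveys
        occurrences_all = dataset.occurrences
        ranks = {sp.species_id: sp.rsgcn_rank for sp in dataset.species}
        if out is not None:
            dataset.write_csvs(out / "inputs")
    aux = aux.set_index("catchment_id")

    # the modelling dataset: records and survey events from cutoff_year on
    occurrences = dm.filter_records_by_year(occurrences_all, config.cutoff_year_model)
    surveys = dm.filter_records_by_year(surveys_all, config.cutoff_year_model)
    frame = frame.with_survey_counts(surveys)
    presences = dm.consolidate_presences(occurrences, frame)
    species_ids = sorted(presences)
    if not species_ids:
        raise DataError("no species with occurrence records after year filtering")
    for sp in species_ids:
        ranks.setdefault(sp, "not_listed")
    result = RunResult(
        config=config,
        frame=frame,
        covariates=covariates,
        screening=None,  # set below
        presences=presences,
        rsgcn_ranks=ranks,
        species={},
        warnings=warnings,
        dataset=dataset,
    )
    if stop_idx < STAGES.index("screen"):
        _write_manifest(result, out)
        return result

    # ---- stage: screen -----------------------------------------------------
    rho = dm.spearman_matrix(covariates)
    screening = dm.screen_collinear(
        rho, config.correlation_threshold, config.keep_priority
    )
    retained_cont = [c for c in screening.retained if covariates.kinds[c] == "continuous"]
    if len(retained_cont) >= 2:
        screening.vif = dm.compute_vif(covariates.values(retained_cont))
        for name, v in screening.vif.items():
            if v >= config.vif_limit:
                warnings.append(f"screen: VIF of {name} = {v:.2f} >= {config.vif_limit}")
    retained = covariates.subset(screening.retained)
    result.screening = screening
    if out is not None:
        screening.spearman.to_csv(out / "spearman_matrix.csv")
        (out / "screening_log.txt").write_text(screening.log_text() + "\n")
        pd.DataFrame(
            {"covariate": list(screening.vif), "vif": list(screening.vif.values())}
        ).to_csv(out / "vif.csv", index=False)
    if stop_idx < STAGES.index("background"):
        _write_manifest(result, out)
        return result

    # ---- per-species stages ------------------------------------------------
    all_values = retained.values()  # indexed by catchment_id
    catchment_ids = frame.ids
    binary_maps: dict[str, pd.Series] = {}
    predictions_all: dict[str, pd.Series] = {}
    for idx, sp in enumerate(species_ids):
        stage = "background"
        try:
            candidates = bg.eligible_background(frame, presences[sp])
            weights = bg.selection_weights(
                candidates, frame, config.weight_mode, config.background_floor_frac
            )
            bg_cfg = bg.BackgroundConfig(
                n_background=config.n_background,
                weight_mode=config.weight_mode,
                floor_frac=config.background_floor_frac,
                seed=_derive_seed(config.seed, 1, idx),
            )
            selected = bg.sample_background(candidates, weights, bg_cfg)
            if out is not None:
                bg.background_audit(candidates, weights, selected).to_csv(
                    out / f"background_{sp}.csv", index=False
                )
            if stop_idx < STAGES.index("fit"):
                continue

            stage = "fit"
            layer = dm.huc8_occurrence_layer(presences, frame, sp)
            sp_table = retained.with_column(
                layer.name, layer, kind="binary", scale="huc8"
            )
            sp_values = sp_table.values()
            kinds = sp_table.kinds
            pres_ids = sorted(presences[sp])
            # presences join the normalization pool (the packaged MaxEnt
            # add-samples-to-background default): with presences excluded
            # from the contrast set, their feature mean can fall outside the
            # background hull and the penalized optimum escapes to infinity
            fit_pool = sorted(set(selected) | set(pres_ids))
            fs = mx.expand_features(
                sp_values, fit_pool, kinds, config.feature_classes, config.n_knots
            )
            f_pool = fs.transform(sp_values.loc[fit_pool])
            f_bg = fs.transform(sp_values.loc[selected])
            f_pres = fs.transform(sp_values.loc[pres_ids])
            tuning = mx.tune_beta(
                f_pres, f_pool, config.beta_grid, contrast_features=f_bg
            )
            for b, msg in tuning.failures.items():
                warnings.append(f"fit[{sp}]: beta={b} skipped: {msg}")
            fit = tuning.fits[tuning.chosen_beta]
            model = mx.SpeciesModel(
                species_id=sp,
                feature_set=fs,
                lam=fit.lam,
                beta_multiplier=tuning.chosen_beta,
                log_normalizer=fit.log_normalizer,
                entropy=fit.entropy,
                n_presence=len(pres_ids),
                background_ids=list(selected),
                output_transform=config.output_transform,
            )
            preds = model.predict(sp_values)
            predictions_all[sp] = preds
            kfold = None
            if len(pres_ids) >= config.k_folds:
                f_all = fs.transform(sp_values)
                sd = mx.kfold_sd(
                    f_pres,
                    f_pool,
                    f_all,
                    tuning.chosen_beta,
                    k=config.k_folds,
                    seed=_derive_seed(config.seed, 2, idx),
                    lam0=fit.lam,
                )
                kfold = pd.Series(sd, index=sp_values.index, name=f"kfold_sd_{sp}")
            else:
                warnings.append(
                    f"fit[{sp}]: only {len(pres_ids)} presences; k-fold SD skipped"
                )
            if out is not None:
                with open(out / f"model_{sp}.json", "w") as fh:
                    json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
                pred_df = pd.DataFrame(
                    {
                        "catchment_id": preds.index,
                        "raw": model.predict(sp_values, transform="raw").to_numpy(),
                        config.output_transform: preds.to_numpy(),
                    }
                )
                if kfold is not None:
                    pred_df["kfold_sd"] = kfold.to_numpy()
                pred_df.to_csv(out / f"predictions_{sp}.csv", index=False)
            if stop_idx < STAGES.index("evaluate"):
                continue

            stage = "evaluate"
            report, binary = ev.evaluate_model(
                sp,
                preds.loc[pres_ids].to_numpy(),
                preds.loc[selected].to_numpy(),
                preds.to_numpy(),
                set(pres_ids),
                preds.index,
                n_windows=config.cbi_n_windows,
                window_width=config.cbi_window_width,
            )
            binary_series = pd.Series(binary, index=preds.index, name=sp)
            binary_maps[sp] = binary_series
            if out is not None:
                pd.DataFrame([report.to_dict()]).to_csv(
                    out / f"evaluation_{sp}.csv", index=False
                )
            result.species[sp] = SpeciesResult(
                species_id=sp,
                model=model,
                tuning=tuning,
                predictions=preds,
                report=report,
                binary=binary_series,
                background_ids=list(selected),
                kfold_sd=kfold,
            )
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed for species {sp!r}: {exc}") from exc

    if stop_idx < STAGES.index("richness") or not binary_maps:
        _write_manifest(result, out)
        return result

    # ---- stage: richness ---------------------------------------------------
    richness = pr.stack_richness(binary_maps, ranks)
    result.richness = richness
    if len(predictions_all) >= 2:
        result.interspecies_rho = pr.interspecies_correlation(
            pd.DataFrame(predictions_all)
        )
        if out is not None:
            result.interspecies_rho.to_csv(out / "interspecies_correlation.csv")
    if out is not None:
        richness.rename_axis("catchment_id").to_csv(out / "richness.csv")
    if stop_idx < STAGES.index("prioritize"):
        _write_manifest(result, out)
        return result

    # ---- stage: prioritize -------------------------------------------------
    recent = dm.filter_records_by_year(surveys_all, config.cutoff_year_survey_binary)
    surveyed_since = set(recent["catchment_id"])
    aux = aux.reindex(frame.ids)
    if aux.isna().any().any():
        raise DataError("priority covariates missing for some catchments")
    survey_surface = pr.survey_priority(richness, surveyed_since)
    restoration = pr.restoration_priority(
        aux["percent_protected"],
        aux["percent_forest"],
        aux["landuse_change_pct"],
        presences,
        frame,
        ranks,
    )
    protection = pr.protection_priority(
        richness, aux["percent_forest"], aux["percent_wetland"], aux["resilience"]
    )
    result.survey_surface = survey_surface
    result.restoration_surfaces = restoration
    result.protection_surface = protection
    try:
        result.protection_vs_protected = pr.protection_vs_protected_correlation(
            protection, aux["percent_protected"], frame.data.set_index("catchment_id")["state"]
        )
    except Exception as exc:  # degenerate only on pathological inputs
        warnings.append(f"prioritize: protection-vs-protected correlation: {exc}")
    result.state_summary = pr.state_summaries(
        frame, richness, surveys, survey_surface, protection, restoration
    )
    if out is not None:
        _write_priority(out, "survey", survey_surface)
        _write_priority(out, "protection", protection)
        for sp, surface in restoration.items():
            _write_priority(out, f"restoration_{sp}", surface)
        result.state_summary.to_csv(out / "state_summary.csv", index=False)
        if result.protection_vs_protected is not None:
            pd.DataFrame(
                {
                    "scope": list(result.protection_vs_protected),
                    "rho": list(result.protection_vs_protected.values()),
                }
            ).to_csv(out / "protection_vs_protected.csv", index=False)
    _write_manifest(result, out)
    return result


def _write_priority(out: Path, name: str, surface: pd.Series) -> None:
    df = surface.rename("score").rename_axis("catchment_id").reset_index()
    ranked = pr.ranked_priority(surface).set_index("catchment_id")["rank"]
    df["rank"] = df["catchment_id"].map(ranked).astype("Int64")
    df.to_csv(out / f"priority_{name}.csv", index=False)


def _write_manifest(result: RunResult, out: Path | None) -> None:
    if out is None:
        return
    manifest = {
        "config": result.config.to_jsonable(),
        "seed": result.config.seed,
        "n_catchments": len(result.frame),
        "species": {
            sp: {
                "chosen_beta": r.tuning.chosen_beta,
                "auc_per_beta": {str(k): v for k, v in sorted(r.tuning.auc_per_beta.items())},
                "n_presence": r.model.n_presence,
                "n_background": len(r.background_ids),
            }
            for sp, r in result.species.items()
        },
        "screening": {
            "dropped": result.screening.dropped if result.screening else [],
            "retained": result.screening.retained if result.screening else [],
            "vif": result.screening.vif if result.screening else {},
        },
        "warnings": result.warnings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
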