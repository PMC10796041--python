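"""End-to-end orchestration: simulate -> features -> fit -> score -> evaluate.

A run is driven by one :class:`RunConfig` (optionally read from YAML) and
writes a self-contained run directory::

    run/
      subjects.tsv  events.tsv          cohort tables (if simulated)
      vocabulary.tsv                    variant, prevalence
      matrix_dev/  matrix_val/          MatrixMarket + sidecars
      index/index.json  index/coefficients.tsv
      scores.tsv                        subject_id, cohort, score, category, charlson
      evaluation.json                   c-indices with CIs, calibration, HRs
      manifest.json                     stage outputs with SHA-256 hashes
      run.log

The development/validation split is temporal: subjects with an index year
at or below ``dev_year_max`` form the development cohort, later years the
validation cohort.  Every stochastic step derives its stream from the
single run seed, so identical config and inputs reproduce byte-identical
coefficients and reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time as _time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes as codes_mod
from . import io as io_mod
from .charlson import charlson_index
from .evaluate import (
    bootstrap_ci,
    calibration_curve,
    harrell_cindex,
    index_correlation,
    stratified_hazard_ratios,
)
from .features import build_design_matrix, save_design_matrix
from .model import categorize_index, fit_penalized_cox, horizon_censor, mdci_score
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(kw_only=True)
class RunConfig:
    out_dir: str
    seed: int | None = None
    # inputs: either paths to tables, or a simulation block
    events_path: str | None = None
    subjects_path: str | None = None
    simulate: SimulationConfig | None = None
    # modelling parameters
    lookback_years: float = 10.0
    horizon_years: float = 10.0
    min_prevalence: float = 1e-4
    alpha_mix: float = 0.5
    n_lambda: int = 100
    n_folds: int = 10
    n_boot: int = 1000
    dev_year_max: int = 2013
    exclusions: tuple = ()
    age_bands: tuple = ((0, 59), (60, 69), (70, 79), (80, 120))

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic step")
        if self.simulate is None and not (self.events_path and self.subjects_path):
            raise ValueError("provide either a simulation block or events/subjects paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import Effect

            eff = sim.pop("effect_spec", None)
            seed = sim.pop("seed", cfg.seed)
            sc = SimulationConfig(**sim, seed=seed)
            if eff is not None:
                sc.effect_spec = [Effect(**e) for e in eff]
            cfg.simulate = sc
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _age_band_labels(ages, bands) -> np.ndarray:
    labels = np.empty(len(ages), dtype=object)
    for lo, hi in bands:
        mask = (ages >= lo) & (ages <= hi)
        labels[mask] = f"age{lo}-{hi}"
    return labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full index-construction and validation pipeline.

    Returns the evaluation report as a dict (also written to
    ``evaluation.json``).
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mdci")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = _time.time()
    artifacts: list[str] = []

    try:
        # -- stage 1: cohort ------------------------------------------------
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            subjects, events = cohort.subjects, cohort.events
            io_mod.write_subjects(subjects, os.path.join(config.out_dir, "subjects.tsv"))
            io_mod.write_events(events, os.path.join(config.out_dir, "events.tsv"))
            artifacts += ["subjects.tsv", "events.tsv"]
            n_dropped = 0
        else:
            events = io_mod.read_events(config.events_path)
            subjects = io_mod.read_subjects(config.subjects_path)
            events, n_dropped = io_mod.clean_event_codes(events)
        io_mod.validate_events(events, subjects)
        logger.info("cohort: %d subjects, %d events (%d malformed codes dropped)",
                    len(subjects), len(events), n_dropped)

        # -- stage 2: temporal split ---------------------------------------
        years = pd.to_datetime(subjects["index_date"]).dt.year
        is_dev = (years <= config.dev_year_max).to_numpy()
        if not is_dev.any() or is_dev.all():
            raise ValueError("temporal split leaves an empty development or validation cohort")
        dev, val = subjects[is_dev], subjects[~is_dev]
        ev_dev = events[events["subject_id"].isin(set(dev["subject_id"]))]
        ev_val = events[events["subject_id"].isin(set(val["subject_id"]))]
        logger.info("split: %d development / %d validation subjects", len(dev), len(val))

        # -- stage 3: vocabulary (development cohort only) ------------------
        vocab = codes_mod.build_vocabulary(
            ev_dev, len(dev), config.min_prevalence, config.exclusions
        )
        vocab.to_frame().to_csv(
            os.path.join(config.out_dir, "vocabulary.tsv"), sep="\t", index=False
        )
        artifacts.append("vocabulary.tsv")
        logger.info("vocabulary: %d variants -> %d candidate predictors",
                    len(vocab), 10 * len(vocab))

        # -- stage 4: design matrices ---------------------------------------
        dm_dev = build_design_matrix(ev_dev, dev, vocab, config.lookback_years)
        dm_val = build_design_matrix(ev_val, val, vocab, config.lookback_years)
        for name, dm in (("matrix_dev", dm_dev), ("matrix_val", dm_val)):
            save_design_matrix(dm, os.path.join(config.out_dir, name))
            artifacts.append(f"{name}/matrix.mtx")

        # -- stage 5: fit ---------------------------------------------------
        t_dev, e_dev = horizon_censor(
            dev["time_days"].to_numpy(), dev["event"].to_numpy(), config.horizon_years
        )
        index = fit_penalized_cox(
            dm_dev.X, t_dev, e_dev,
            alpha_mix=config.alpha_mix, n_lambda=config.n_lambda,
            n_folds=config.n_folds, seed=config.seed, columns=dm_dev.columns,
            metadata={"lookback_years": config.lookback_years,
                      "horizon_years": config.horizon_years},
        )
        index.save(os.path.join(config.out_dir, "index"))
        artifacts += ["index/index.json", "index/coefficients.tsv"]
        logger.info("fit: %d predictors selected at lambda=%.6g",
                    len(index.selected()), index.chosen_lambda)

        # -- stage 6: scores and categories ---------------------------------
        s_dev = mdci_score(index, dm_dev.X)
        s_val = mdci_score(index, dm_val.X)
        cat_val = categorize_index(s_val, index.cutoffs)
        cci_val = charlson_index(ev_val, val.reset_index(drop=True),
                                 lookback_years=config.lookback_years).to_numpy()
        scores_df = pd.concat([
            pd.DataFrame({"subject_id": dm_dev.subject_ids, "cohort": "development",
                          "score": s_dev,
                          "category": categorize_index(s_dev, index.cutoffs)}),
            pd.DataFrame({"subject_id": dm_val.subject_ids, "cohort": "validation",
                          "score": s_val, "category": cat_val,
                          "charlson": cci_val}),
        ])
        scores_df.to_csv(os.path.join(config.out_dir, "scores.tsv"),
                         sep="\t", index=False, float_format="%.10g")
        artifacts.append("scores.tsv")

        # -- stage 7: evaluation on the validation cohort -------------------
        t_val, e_val = horizon_censor(
            val["time_days"].to_numpy(), val["event"].to_numpy(), config.horizon_years
        )
        report: dict = {"n_development": int(len(dev)), "n_validation": int(len(val)),
                        "n_variants": len(vocab), "n_candidate_predictors": 10 * len(vocab),
                        "n_selected_predictors": int(len(index.selected())),
                        "chosen_lambda": float(index.chosen_lambda),
                        "horizons": {}}
        for h in (1, 5, config.horizon_years):
            h = float(h)
            th, eh = horizon_censor(val["time_days"].to_numpy(),
                                    val["event"].to_numpy(), h)
            entry = {"cindex_mdci": harrell_cindex(s_val, th, eh),
                     "cindex_charlson": harrell_cindex(cci_val, th, eh)}
            if config.n_boot >= 2:
                entry["cindex_mdci_ci"] = bootstrap_ci(
                    harrell_cindex, (s_val, th, eh),
                    n_boot=config.n_boot, seed=config.seed)
                entry["cindex_charlson_ci"] = bootstrap_ci(
                    harrell_cindex, (cci_val, th, eh),
                    n_boot=config.n_boot, seed=config.seed)
            report["horizons"][f"{h:g}y"] = entry
        calib = calibration_curve(s_val, t_val, e_val, config.horizon_years)
        report["calibration"] = {
            "horizon_years": config.horizon_years,
            "bins": calib.bins.to_dict(orient="records"),
            "max_abs_gap": calib.max_abs_gap(),
        }
        strata = _age_band_labels(val["age"].to_numpy(), config.age_bands)
        hr = stratified_hazard_ratios(cat_val, strata,
                                      val["time_days"].to_numpy(),
                                      val["event"].to_numpy())
        report["hazard_ratios_1y"] = hr.to_dict(orient="records")
        corr = index_correlation(s_val, cci_val.astype(float)) \
            if len(np.unique(cci_val)) > 1 else None
        report["spearman_mdci_charlson"] = corr

        with open(os.path.join(config.out_dir, "evaluation.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        artifacts.append("evaluation.json")

        manifest = {a: _sha256(os.path.join(config.out_dir, a)) for a in artifacts}
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        logger.info("pipeline finished in %.1f s", _time.time() - t0)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
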