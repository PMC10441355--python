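"""Canonical synthetic study configurations.

These name the default conditions every entry point (tests, analysis
drivers, the acceptance script) exercises, so the study design lives in
one place:

* the multi-tissue rat aging panel (the generator defaults: 240 samples
  over four tissues, 2,000 probes, 200 aging CpGs, ages 0.04-2.3 y);
* the two-species human+rat panel sharing a relative-age signal
  (150 + 150 samples spanning each species' full lifespan);
* the three-arm treatment study (young 30 weeks = 0.58 y, old 109 weeks
  = 2.1 y, n = 6 per arm per tissue) with a planted rejuvenation,
  paired with an independent training panel drawn from the same CpG
  population.
"""

from __future__ import annotations

import pandas as pd

from .clocks import AgeTransform, cross_validate, fit_clock, predict_age
from .evaluation import RejuvenationReport, summarize_rejuvenation
from .simulate import (
    MethylSimConfig,
    TreatmentSimConfig,
    simulate_methylomes,
    simulate_treatment_study,
    simulate_two_species,
)

__all__ = [
    "default_rat_panel_config",
    "two_species_configs",
    "rejuvenation_study_config",
    "run_pan_tissue_cv",
    "run_two_species_cv",
    "run_rejuvenation_recovery",
]


def default_rat_panel_config(seed: int = 1) -> MethylSimConfig:
    """The standard rat multi-tissue panel: generator defaults + seed."""
    return MethylSimConfig(seed=seed)


def two_species_configs(
    seed: int = 2,
) -> tuple[MethylSimConfig, MethylSimConfig]:
    """150 rat + 150 human samples, full lifespans, shared probe panel."""
    rat = MethylSimConfig(
        tissues={"blood": 75, "liver": 75},
        age_range=(0.0, 3.8),
        seed=seed,
    )
    human = MethylSimConfig(
        species="human",
        tissues={"blood": 75, "liver": 75},
        age_range=(0.0, 122.5),
        seed=seed,
    )
    return rat, human


def rejuvenation_study_config(
    seed: int,
    planted_rejuvenation: float = 67.40,
) -> TreatmentSimConfig:
    """Four-tissue three-arm study with the planted rejuvenation percent."""
    return TreatmentSimConfig(
        base=MethylSimConfig(seed=seed),
        planted_rejuvenation=planted_rejuvenation,
        seed=seed + 1000,
    )


def run_pan_tissue_cv(seed: int = 1, scheme: str | int = "loocv"):
    """Cross-validate the pan-tissue clock on the standard rat panel."""
    cfg = default_rat_panel_config(seed)
    m, ann, _ = simulate_methylomes(cfg)
    return cross_validate(m, ann, AgeTransform("identity"), scheme=scheme,
                          seed=seed)


def run_two_species_cv(seed: int = 2, scheme: str | int = 10):
    """Cross-validate the combined relative-age clock; report per species.

    Returns the CV report plus the rat-only and human-only Pearson
    correlations of held-out predictions against chronological age.
    """
    import numpy as np

    cfg_rat, cfg_human = two_species_configs(seed)
    m, ann, _ = simulate_two_species(cfg_rat, cfg_human,
                                     shared_relative_age_signal=True)
    report = cross_validate(m, ann, AgeTransform("relative"), scheme=scheme,
                            seed=seed)
    by_species = {}
    for species, sub in report.predictions.groupby("species"):
        by_species[species] = float(
            np.corrcoef(sub["dnam_age"], sub["age"])[0, 1]
        )
    return report, by_species


def run_rejuvenation_recovery(
    seed: int,
    planted_rejuvenation: float = 67.40,
) -> RejuvenationReport:
    """Full rejuvenation pipeline for one seed.

    Trains a per-tissue clock on an independent panel from the same CpG
    population, predicts all three arms of the treatment study, and
    summarizes per-tissue and grand-average rejuvenation.
    """
    cfg = rejuvenation_study_config(seed, planted_rejuvenation)
    train_m, train_ann, _ = simulate_methylomes(cfg.base)
    study_m, study_ann, _ = simulate_treatment_study(cfg)
    frames = []
    for tissue in cfg.base.tissues:
        clock = fit_clock(train_m, train_ann, AgeTransform("identity"),
                          tissue_filter=[tissue], seed=seed)
        keep = study_ann[study_ann["tissue"] == tissue]
        pred = predict_age(clock, study_m.select_samples(keep["sample_id"]),
                           keep)
        pred["clock"] = f"{tissue}_clock"
        frames.append(pred)
    return summarize_rejuvenation(pd.concat(frames, ignore_index=True))
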