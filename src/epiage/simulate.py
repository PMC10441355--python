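"""Synthetic methylation and glycan datasets with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* aging CpGs whose logit(beta) is linear in *relative age*
  (age / species maximum lifespan), half gaining and half losing
  methylation by default;
* tissue- and batch-structured nuisance variation in logit units;
* a three-arm treatment study (young control / old control / old treated)
  in which the treated arm is generated at a *reduced effective age* —
  so the planted rejuvenation percentage is exactly the quantity the
  downstream rejuvenation statistic estimates;
* a two-species (rat + human) panel which can share a relative-age signal
  across species;
* a longitudinal two-timepoint IgG glycoform panel with per-subject random
  intercepts, an aging drift toward agalactosylation and a planted
  treatment reversal.

Probe-level parameters (baselines, slopes, which probes age, tissue
offsets) are drawn from the config seed alone, so two datasets generated
from configs sharing a seed describe the same CpG population: a clock
trained on one transfers to the other.  Sample-level draws use separate
streams of the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_methylation import BetaMatrix, ValidationError, validate_annotation

__all__ = [
    "MethylSimConfig",
    "TreatmentSimConfig",
    "GlycanSimConfig",
    "simulate_methylomes",
    "simulate_treatment_study",
    "simulate_two_species",
    "simulate_glycan_study",
]

DEFAULT_MAX_LIFESPAN = {"rat": 3.8, "human": 122.5}

# stream tags separating probe-level from sample-level randomness
_PROBE_STREAM = 101
_SAMPLE_STREAM = 202
_GLYCAN_STREAM = 303


@dataclasses.dataclass
class MethylSimConfig:
    """Configuration for one species' methylome panel.

    Defaults describe the standard synthetic rat multi-tissue panel:
    240 samples over four tissues, 2,000 probes of which 200 age, logit
    slope magnitudes ~ Normal(4, 1) against relative age, measurement
    noise sd 0.03 on the beta scale.  Ages span 0.04-2.3 years, the span
    of the rat profiles the clocks are built from.
    """

    n_probes: int = 2000
    n_age_probes: int = 200
    frac_gain: float = 0.5
    tissues: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"blood": 60, "liver": 60, "heart": 60,
                                 "hypothalamus": 60}
    )
    age_range: tuple[float, float] = (0.04, 2.3)
    species: str = "rat"
    max_lifespan: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MAX_LIFESPAN)
    )
    slope_mean: float = 4.0
    slope_sd: float = 1.0
    baseline_sd: float = 1.0
    logit_slope_scale: float = 1.0
    tissue_offset_sd: float = 0.3
    batch_effect_sd: float = 0.2
    noise_sd: float = 0.03
    samples_per_plate: int = 12
    n_array_columns: int = 6
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_age_probes <= self.n_probes:
            raise ValidationError("n_age_probes must be within [0, n_probes]")
        if not 0.0 <= self.frac_gain <= 1.0:
            raise ValidationError("frac_gain must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.species not in self.max_lifespan:
            raise ValidationError(f"no max lifespan for species {self.species!r}")
        lo, hi = self.age_range
        if not 0 <= lo < hi <= self.max_lifespan[self.species]:
            raise ValidationError(
                "age_range must be within [0, species max lifespan]"
            )
        if not self.tissues or any(n < 1 for n in self.tissues.values()):
            raise ValidationError("each tissue needs at least one sample")

    @property
    def n_samples(self) -> int:
        return int(sum(self.tissues.values()))


@dataclasses.dataclass
class TreatmentSimConfig:
    """Three-arm treatment study: young / old control / old treated.

    Defaults mirror the treatment experiment's design: 6 animals per arm,
    young at 30 weeks (0.58 y), old at 109 weeks (2.1 y).  The treated arm
    is *generated* at effective age ``old_age * (1 - planted_rejuvenation/100)``
    but annotated with its chronological old age.
    """

    base: MethylSimConfig = dataclasses.field(default_factory=MethylSimConfig)
    n_per_group: int = 6
    young_age: float = 0.58
    old_age: float = 2.1
    planted_rejuvenation: float = 67.40
    seed: int = 0

    def validate(self) -> None:
        self.base.validate()
        if not 0.0 <= self.planted_rejuvenation <= 100.0:
            raise ValidationError("planted_rejuvenation must be in [0, 100]")
        if not 0 <= self.young_age < self.old_age:
            raise ValidationError("need 0 <= young_age < old_age")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")

    @property
    def treated_effective_age(self) -> float:
        return self.old_age * (1.0 - self.planted_rejuvenation / 100.0)


@dataclasses.dataclass
class GlycanSimConfig:
    """Two-timepoint IgG glycoform study, treated vs control arms.

    Baseline compositions and drifts emulate glycan aging: the
    agalactosylated glycoform (G0) rises with time in untreated animals
    while the digalactosylated form (G2) falls; treatment reverses both.
    Drifts and treatment shifts sum to zero within each subclass so the
    noise-free composition stays on the simplex.
    """

    n_per_arm: int = 6
    subclasses: Sequence[str] = ("IgG2a", "IgG2b", "IgG2c")
    glycoforms: Sequence[str] = ("G0", "G1", "G2")
    baseline_props: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "IgG2a": {"G0": 0.50, "G1": 0.30, "G2": 0.20},
            "IgG2b": {"G0": 0.45, "G1": 0.35, "G2": 0.20},
            "IgG2c": {"G0": 0.40, "G1": 0.35, "G2": 0.25},
        }
    )
    age_slopes: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"G0": 0.04, "G1": -0.01, "G2": -0.03}
    )
    treatment_effect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"G0": -0.05, "G1": 0.01, "G2": 0.04}
    )
    subject_intercept_sd: float = 0.02
    residual_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 2:
            raise ValidationError("n_per_arm must be >= 2")
        for sc in self.subclasses:
            props = self.baseline_props[sc]
            total = sum(props[g] for g in self.glycoforms)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"baseline_props for {sc} sum to {total}, expected 1"
                )
            for g in self.glycoforms:
                drifted = props[g] + self.age_slopes.get(g, 0.0)
                treated = drifted + self.treatment_effect.get(g, 0.0)
                if not (0.0 < drifted < 1.0 and 0.0 < treated < 1.0):
                    raise ValidationError(
                        f"expected proportion for {sc}/{g} leaves (0, 1) "
                        "before renormalization"
                    )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _probe_params(cfg: MethylSimConfig) -> dict:
    """Probe-level population parameters, a deterministic function of seed."""
    rng = _rng(cfg.seed, _PROBE_STREAM)
    probe_ids = np.array([f"cg{i:06d}" for i in range(cfg.n_probes)], dtype=object)
    baselines = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_probes)
    age_idx = np.sort(rng.choice(cfg.n_probes, size=cfg.n_age_probes,
                                 replace=False))
    slopes = np.zeros(cfg.n_probes)
    magnitudes = np.abs(rng.normal(cfg.slope_mean, cfg.slope_sd,
                                   size=cfg.n_age_probes))
    n_gain = int(round(cfg.frac_gain * cfg.n_age_probes))
    signs = np.concatenate([np.ones(n_gain), -np.ones(cfg.n_age_probes - n_gain)])
    rng.shuffle(signs)
    slopes[age_idx] = cfg.logit_slope_scale * magnitudes * signs
    tissue_names = list(cfg.tissues)
    tissue_offsets = rng.normal(0.0, cfg.tissue_offset_sd,
                                size=(cfg.n_probes, len(tissue_names)))
    return {
        "probe_ids": probe_ids,
        "baselines": baselines,
        "age_probe_idx": age_idx,
        "slopes": slopes,
        "tissue_names": tissue_names,
        "tissue_offsets": tissue_offsets,
    }


def _generate_betas(
    cfg: MethylSimConfig,
    params: dict,
    ages_effective: np.ndarray,
    tissue_idx: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core generative model: beta = clip01(invlogit(linear predictor) + noise)."""
    n = len(ages_effective)
    rel_age = ages_effective / cfg.max_lifespan[cfg.species]
    n_plates = max(1, int(np.ceil(n / cfg.samples_per_plate)))
    # samples are placed on plates in random order, as array randomization
    # would do in practice (also keeps batch separable from biology)
    position = rng.permutation(n)
    plate_idx = position // cfg.samples_per_plate
    col_idx = position % cfg.n_array_columns
    plate_effects = rng.normal(0.0, cfg.batch_effect_sd,
                               size=(cfg.n_probes, n_plates))
    col_effects = rng.normal(0.0, cfg.batch_effect_sd / 2.0,
                             size=(cfg.n_probes, cfg.n_array_columns))
    lin = (
        params["baselines"][:, None]
        + params["slopes"][:, None] * rel_age[None, :]
        + params["tissue_offsets"][:, tissue_idx]
        + plate_effects[:, plate_idx]
        + col_effects[:, col_idx]
    )
    betas = expit(lin)
    if cfg.noise_sd > 0:
        betas = betas + rng.normal(0.0, cfg.noise_sd, size=lin.shape)
    return np.clip(betas, 0.0, 1.0), plate_idx, col_idx


def _annotation(
    cfg: MethylSimConfig,
    sample_ids: np.ndarray,
    ages_chrono: np.ndarray,
    tissue_idx: np.ndarray,
    plate_idx: np.ndarray,
    col_idx: np.ndarray,
    groups: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tissue_names = list(cfg.tissues)
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species": cfg.species,
            "tissue": [tissue_names[t] for t in tissue_idx],
            "age": ages_chrono,
            "sex": rng.choice(["F", "M"], size=len(sample_ids)),
            "batch_plate": [f"plate{p + 1:02d}" for p in plate_idx],
            "batch_column": [f"col{c + 1}" for c in col_idx],
            "group": groups,
        }
    )
    return validate_annotation(ann)


def simulate_methylomes(
    cfg: MethylSimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, dict]:
    """Cross-sectional multi-tissue panel with ages uniform on ``age_range``."""
    cfg.validate()
    params = _probe_params(cfg)
    rng = _rng(cfg.seed, _SAMPLE_STREAM)
    tissue_idx = np.concatenate(
        [np.full(n, k, dtype=int) for k, n in enumerate(cfg.tissues.values())]
    )
    n = cfg.n_samples
    ages = rng.uniform(*cfg.age_range, size=n)
    betas, plate_idx, col_idx = _generate_betas(cfg, params, ages, tissue_idx, rng)
    prefix = cfg.species[0]
    sample_ids = np.array([f"{prefix}s{i:04d}" for i in range(n)], dtype=object)
    ann = _annotation(cfg, sample_ids, ages, tissue_idx, plate_idx, col_idx,
                      np.array(["none"] * n, dtype=object), rng)
    m = BetaMatrix(params["probe_ids"], sample_ids, betas)
    truth = _truth_record(cfg, params)
    return m, ann, truth


def simulate_treatment_study(
    cfg: TreatmentSimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, dict]:
    """Three-arm study; treated methylomes drawn at a reduced effective age."""
    cfg.validate()
    base = cfg.base
    params = _probe_params(base)
    rng = _rng(cfg.seed, _SAMPLE_STREAM + 1)
    tissue_names = list(base.tissues)
    per_tissue = cfg.n_per_group * 3
    tissue_idx = np.repeat(np.arange(len(tissue_names)), per_tissue)
    group_cycle = (
        ["young_control"] * cfg.n_per_group
        + ["old_control"] * cfg.n_per_group
        + ["old_treated"] * cfg.n_per_group
    )
    groups = np.array(group_cycle * len(tissue_names), dtype=object)
    age_by_group = {
        "young_control": (cfg.young_age, cfg.young_age),
        "old_control": (cfg.old_age, cfg.old_age),
        "old_treated": (cfg.old_age, cfg.treated_effective_age),
    }
    ages_chrono = np.array([age_by_group[g][0] for g in groups])
    ages_eff = np.array([age_by_group[g][1] for g in groups])
    betas, plate_idx, col_idx = _generate_betas(base, params, ages_eff,
                                                tissue_idx, rng)
    sample_ids = np.array(
        [f"tx{i:04d}" for i in range(len(groups))], dtype=object
    )
    ann = _annotation(base, sample_ids, ages_chrono, tissue_idx, plate_idx,
                      col_idx, groups, rng)
    m = BetaMatrix(params["probe_ids"], sample_ids, betas)
    truth = _truth_record(base, params)
    truth.update(
        {
            "planted_rejuvenation_percent": cfg.planted_rejuvenation,
            "young_age": cfg.young_age,
            "old_age": cfg.old_age,
            "treated_effective_age": cfg.treated_effective_age,
            "n_per_group": cfg.n_per_group,
            "study_seed": cfg.seed,
        }
    )
    return m, ann, truth


def simulate_two_species(
    cfg_rat: MethylSimConfig,
    cfg_human: MethylSimConfig,
    shared_relative_age_signal: bool = True,
) -> tuple[BetaMatrix, pd.DataFrame, dict]:
    """Combined rat + human panel on one probe set.

    With the shared signal, the same probes carry the same logit slope
    against relative age in both species, so a rat at half its lifespan and
    a human at half theirs have identical expected betas at signal probes.
    """
    cfg_rat.validate()
    cfg_human.validate()
    if cfg_rat.n_probes != cfg_human.n_probes:
        raise ValidationError("both species must use the same probe panel size")
    params_rat = _probe_params(cfg_rat)
    if shared_relative_age_signal:
        params_human = {**params_rat}
    else:
        params_human = _probe_params(cfg_human)
        if cfg_human.seed == cfg_rat.seed:
            raise ValidationError(
                "independent signals need distinct seeds for the two species"
            )
    # human tissue offsets must be drawn for the human tissue list
    rng_h = _rng(cfg_human.seed, _PROBE_STREAM + 7)
    params_human = {
        **params_human,
        "tissue_names": list(cfg_human.tissues),
        "tissue_offsets": rng_h.normal(
            0.0, cfg_human.tissue_offset_sd,
            size=(cfg_human.n_probes, len(cfg_human.tissues)),
        ),
    }

    frames = []
    anns = []
    for cfg, params, tag in (
        (cfg_rat, params_rat, "rat"),
        (cfg_human, params_human, "human"),
    ):
        rng = _rng(cfg.seed, _SAMPLE_STREAM + 2)
        tissue_idx = np.concatenate(
            [np.full(n, k, dtype=int) for k, n in enumerate(cfg.tissues.values())]
        )
        ages = rng.uniform(*cfg.age_range, size=cfg.n_samples)
        betas, plate_idx, col_idx = _generate_betas(cfg, params, ages,
                                                    tissue_idx, rng)
        sample_ids = np.array(
            [f"{tag}{i:04d}" for i in range(cfg.n_samples)], dtype=object
        )
        frames.append(
            pd.DataFrame(betas, index=params_rat["probe_ids"],
                         columns=sample_ids)
        )
        anns.append(
            _annotation(cfg, sample_ids, ages, tissue_idx, plate_idx, col_idx,
                        np.array(["none"] * cfg.n_samples, dtype=object), rng)
        )
    combined = pd.concat(frames, axis=1)
    combined.index.name = "probe_id"
    m = BetaMatrix.from_frame(combined)
    ann = pd.concat(anns, ignore_index=True)
    truth = _truth_record(cfg_rat, params_rat)
    truth["shared_relative_age_signal"] = bool(shared_relative_age_signal)
    if not shared_relative_age_signal:
        truth["human_age_probes"] = [
            str(params_human["probe_ids"][i])
            for i in params_human["age_probe_idx"]
        ]
        truth["human_slopes"] = params_human["slopes"][
            params_human["age_probe_idx"]
        ].tolist()
    return m, ann, truth


def simulate_glycan_study(cfg: GlycanSimConfig) -> tuple[pd.DataFrame, dict]:
    """Longitudinal glycoform table (long format) with planted effects.

    Columns: sample_id, subject_id, arm, timepoint, subclass, glycoform,
    relative_abundance; compositions renormalized to the simplex within
    each sample x subclass.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _GLYCAN_STREAM)
    rows = []
    glycoforms = list(cfg.glycoforms)
    for arm in ("control", "treated"):
        for i in range(cfg.n_per_arm):
            subject = f"{arm}{i:02d}"
            intercepts = {
                (sc, g): rng.normal(0.0, cfg.subject_intercept_sd)
                for sc in cfg.subclasses
                for g in glycoforms
            }
            for timepoint in ("baseline", "followup"):
                sample_id = f"{subject}_{timepoint}"
                for sc in cfg.subclasses:
                    raw = np.empty(len(glycoforms))
                    for j, g in enumerate(glycoforms):
                        mu = cfg.baseline_props[sc][g] + intercepts[(sc, g)]
                        if timepoint == "followup":
                            mu += cfg.age_slopes.get(g, 0.0)
                            if arm == "treated":
                                mu += cfg.treatment_effect.get(g, 0.0)
                        raw[j] = mu + rng.normal(0.0, cfg.residual_sd)
                    raw = np.clip(raw, 1e-6, None)
                    props = raw / raw.sum()
                    for j, g in enumerate(glycoforms):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "subject_id": subject,
                                "arm": arm,
                                "timepoint": timepoint,
                                "subclass": sc,
                                "glycoform": g,
                                "relative_abundance": props[j],
                            }
                        )
    table = pd.DataFrame(rows)
    truth = {
        "age_slopes": dict(cfg.age_slopes),
        "treatment_effect": dict(cfg.treatment_effect),
        "n_per_arm": cfg.n_per_arm,
        "seed": cfg.seed,
    }
    return table, truth


def _truth_record(cfg: MethylSimConfig, params: dict) -> dict:
    age_idx = params["age_probe_idx"]
    return {
        "species": cfg.species,
        "max_lifespan": dict(cfg.max_lifespan),
        "age_probes": [str(params["probe_ids"][i]) for i in age_idx],
        "slopes": params["slopes"][age_idx].tolist(),
        "baselines": params["baselines"][age_idx].tolist(),
        "n_probes": cfg.n_probes,
        "n_age_probes": cfg.n_age_probes,
        "frac_gain": cfg.frac_gain,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
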