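#!/usr/bin/env python
"""Generate the synthetic study datasets and write them to disk.

Produces four datasets under scratch/data/ (regenerable from seed):

* ``rat_panel``    — the default multi-tissue rat aging panel
  (240 samples x 2,000 probes, 200 planted aging CpGs);
* ``two_species``  — 150 rat + 150 human samples sharing a relative-age
  signal;
* ``treatment``    — the three-arm four-tissue treatment study with a
  67.40% planted rejuvenation;
* ``glycans``      — the longitudinal two-timepoint IgG glycoform panel.

Each dataset ships with its ground-truth JSON so every later stage can be
scored against what was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from epiage.io_methylation import write_beta_matrix, write_sample_annotation
from epiage.simulate import (
    GlycanSimConfig,
    simulate_glycan_study,
    simulate_methylomes,
    simulate_treatment_study,
    simulate_two_species,
    write_truth,
)
from epiage.studies import (
    default_rat_panel_config,
    rejuvenation_study_config,
    two_species_configs,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def save_methyl(name, m, ann, truth):
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(m, d / "betas.tsv")
    write_sample_annotation(ann, d / "samples.csv")
    write_truth(truth, d / "truth.json")
    print(f"{name}: {m.n_probes} probes x {m.n_samples} samples -> {d}")


def main():
    m, ann, truth = simulate_methylomes(default_rat_panel_config(SEED))
    save_methyl("rat_panel", m, ann, truth)

    cfg_rat, cfg_human = two_species_configs(SEED + 1)
    m, ann, truth = simulate_two_species(cfg_rat, cfg_human)
    save_methyl("two_species", m, ann, truth)

    tcfg = rejuvenation_study_config(SEED)
    m, ann, truth = simulate_treatment_study(tcfg)
    save_methyl("treatment", m, ann, truth)
    print(f"  planted rejuvenation: {tcfg.planted_rejuvenation}% "
          f"(treated arm generated at {tcfg.treated_effective_age:.3f} y)")

    table, truth = simulate_glycan_study(GlycanSimConfig(seed=SEED))
    d = OUT / "glycans"
    d.mkdir(parents=True, exist_ok=True)
    table.to_csv(d / "glycoforms.csv", index=False, float_format="%.10g")
    write_truth(truth, d / "truth.json")
    print(f"glycans: {table['subject_id'].nunique()} subjects, "
          f"2 timepoints -> {d}")


if __name__ == "__main__":
    main()
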