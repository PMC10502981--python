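#!/usr/bin/env python
"""Generate demonstration cohorts for the downstream analyses.

Writes a small two-exposure cohort and a mediation cohort (PLINK .raw
dosages, phenotype CSV, truth YAML) under results/cohorts/, and prints
the realised instrument strength so the regimes are visible.
"""

import argparse
from pathlib import Path

from collidermr.instruments import mean_f_statistic
from collidermr.io import write_dosage_raw, write_truth_yaml
from collidermr.simulate import (
    SimulationConfig,
    simulate_mediation_cohort,
    simulate_two_exposure_cohort,
)
from collidermr.studies import MEDIATION_CONFIG, WEAK_PLEIOTROPY_CONFIG

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n", type=int, default=500, help="cohort size for the demo files")
ap.add_argument("--out-dir", default="results/cohorts")
args = ap.parse_args()

out = Path(args.out_dir)
out.mkdir(parents=True, exist_ok=True)

for name, base, gen in (
    ("two_exposure", WEAK_PLEIOTROPY_CONFIG, simulate_two_exposure_cohort),
    ("mediation", MEDIATION_CONFIG, simulate_mediation_cohort),
):
    cfg_fields = dict(base)
    cfg_fields["n_individuals"] = args.n
    cfg = SimulationConfig(seed=args.seed, **cfg_fields)
    geno, cohort, truth = gen(cfg)
    write_dosage_raw(geno, out / f"{name}.raw")
    cohort.to_csv(out / f"{name}.csv", index=False)
    write_truth_yaml(truth, out / f"{name}.truth.yaml")
    xcol = "x1" if name == "two_exposure" else "x"
    f = mean_f_statistic(
        geno.values(truth.snp_ids_x1), cohort[xcol].to_numpy()
    )
    print(
        f"{name}: n={geno.n}, m={geno.m} SNPs, "
        f"mean per-SNP F={f['mean_f']:.1f}, joint F={f['joint_f']:.1f}"
    )
print(f"cohort files under {out}/")
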