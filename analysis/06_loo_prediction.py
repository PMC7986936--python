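"""Predictive validity: leave-one-out prediction of group and CAG.

For each subject in turn, the hierarchical model is re-estimated on the
remaining subjects and the held-out subject's diagnostic group (and, for
gene carriers, CAG-repeat length) is predicted from their brain data alone.
"""

import argparse
from pathlib import Path

import pandas as pd

from hdprog.synthetic import CohortConfig, generate_cohort
from hdprog.validation import loo_predict

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--n-per-group", type=int, default=20)
parser.add_argument("--out", type=Path, default=Path("results/loo"))
args = parser.parse_args()

config = CohortConfig(seed=args.seed, n_hd=args.n_per_group,
                      n_control=args.n_per_group)
subjects, series = generate_cohort(config)
args.out.mkdir(parents=True, exist_ok=True)

loo_g = loo_predict(subjects, series, "group")
pd.DataFrame({"subject": loo_g.subject_ids, "true": loo_g.true_values,
              "predicted": loo_g.predicted,
              "p_hd": loo_g.uncertainty}).to_csv(
    args.out / "loo_group.tsv", sep="\t", index=False, float_format="%.5g")
n = len(loo_g.true_values)
correct = int(round(loo_g.accuracy * n))
print(f"group prediction: {correct} of {n} correctly assigned "
      f"(accuracy {loo_g.accuracy:.2f}, r = {loo_g.r:.2f})")

loo_c = loo_predict(subjects, series, "CAG")
pd.DataFrame({"subject": loo_c.subject_ids, "true": loo_c.true_values,
              "predicted": loo_c.predicted,
              "sd": loo_c.uncertainty}).to_csv(
    args.out / "loo_cag.tsv", sep="\t", index=False, float_format="%.5g")
print(f"CAG prediction: r = {loo_c.r:.2f} over {len(loo_c.true_values)} "
      f"gene carriers")
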