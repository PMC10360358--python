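"""Univariate median-split Cox / log-rank screen of the cohort features
against PFS, with BH FDR, followed by resampled penalized-Cox variable
importance.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cdkres.io import read_clinical, write_results
from cdkres.survival import multivariate_importance, univariate_screen

SEED = 20240901

base = Path(__file__).resolve().parent.parent
results = base / "results"
clinical = read_clinical(results / "cohort" / "clinical.tsv")

# join the derived features produced by the earlier stages
scars = pd.read_csv(results / "scar_scores.tsv", sep="\t").rename(columns={"sample": "patient"})
expo = pd.read_csv(results / "signature_exposures.tsv", sep="\t").rename(
    columns={"sample": "patient"}
)
exprf = pd.read_csv(results / "expression_features.tsv", sep="\t").rename(
    columns={"sample": "patient"}
)
table = (
    clinical.merge(scars, on="patient")
    .merge(expo[["patient", "S1", "S3", "S13"]], on="patient")
    .merge(exprf[["patient", "proliferative_index", "cyt"]], on="patient")
)

features = ["hrd_high", "hrd_index", "loh", "tai", "lst", "cin", "S3", "S13",
            "proliferative_index", "cyt"]
screen = univariate_screen(table, features)
write_results(screen, results / "survival_screen.tsv")

sig = screen[screen["logrank_p"] < 0.05]
print(f"screened {len(screen)} features against PFS in {len(table)} patients")
print(f"  significant at p<0.05: {sig['feature'].tolist()}")
row = screen.set_index("feature").loc["hrd_high"]
print(f"  planted prognostic factor hrd_high: HR={row['hr']:.2f} "
      f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], log-rank p={row['logrank_p']:.3g}, "
      f"q={row['q']:.3g}")

imp = multivariate_importance(
    table, [f for f in features if f != "hrd_index"],  # drop the sum of loh/tai/lst
    n_resamples=100, seed=SEED,
)
write_results(imp, results / "survival_importance.tsv")
print("  top importance:", ", ".join(
    f"{r.feature} ({r.importance:.2f})" for r in imp.head(3).itertuples()))
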