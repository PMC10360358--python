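"""Expression-derived features: proliferative index, CYT score, and
nearest-centroid subtype calls; checks the planted proliferative shift.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cdkres.expression import cyt_score, log2_tpm, pam50_classify, proliferative_index
from cdkres.io import read_expression, write_results

base = Path(__file__).resolve().parent.parent
cohort = base / "results" / "cohort"
tpm = read_expression(cohort / "expression.tsv")
logm = log2_tpm(tpm)

table = pd.DataFrame({"sample": tpm.columns})
table["proliferative_index"] = proliferative_index(tpm).values
table["cyt"] = cyt_score(tpm).values
table = table.merge(pam50_classify(logm)[["sample", "subtype"]], on="sample")
write_results(table, base / "results" / "expression_features.tsv")

truth = json.loads((cohort / "ground_truth.json").read_text())
groups = pd.Series(truth["prolif_group"])
pi = table.set_index("sample")["proliferative_index"]
ratio = np.exp(np.log(pi[groups == 1]).mean() - np.log(pi[groups == 0]).mean())
print(f"computed expression features for {len(table)} samples")
print(f"  planted 1-log2-unit proliferative shift -> geometric-mean ratio {ratio:.2f} (expect ~2)")
print(f"  subtype calls: {table['subtype'].value_counts().to_dict()}")
planted_sub = pd.Series(truth["subtypes"])
acc = (table.set_index("sample")["subtype"] == planted_sub).mean()
print(f"  planted subtype labels recovered in {acc:.0%} of samples")
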