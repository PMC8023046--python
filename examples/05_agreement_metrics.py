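"""Agreement statistics: confusion metrics, kappa, Kendall's W, chi-square."""

import numpy as np
import pandas as pd

from lungsound.metrics import (
    chi_square,
    cohens_kappa,
    f1_score,
    kendalls_w,
    round1,
)

# Per-class F1 from a sensitivity/precision operating point
print("F1 of (sensitivity 81.3%, precision 80.6%):",
      round1(f1_score(81.3, 80.6)), "%")

# Two raters with imperfect agreement
rng = np.random.default_rng(0)
ids = [f"r{i}" for i in range(120)]
truth = pd.Series(rng.choice(["crackle", "wheeze", "normal"], 120), index=ids)
rater = truth.copy()
flip = rng.random(120) < 0.25
rater[flip] = rng.choice(["crackle", "wheeze", "normal"], flip.sum())
k = cohens_kappa(truth, rater)
print(f"Cohen's kappa: {k.kappa:.3f} (95% CI {k.ci_low:.3f}-{k.ci_high:.3f})")

# Concordance of several raters over the same recordings
ratings = pd.DataFrame([truth.values, rater.values, truth.values])
print(f"Kendall's W over 3 raters x 120 recordings: {kendalls_w(ratings):.3f}")

stat, dof, p = chi_square([[20, 10], [10, 20]])
print(f"chi-square on [[20,10],[10,20]]: statistic {stat:.3f}, df {dof}, p {p:.4f}")
print("\nKappa above 0.8 is 'almost perfect' two-rater agreement; W is the "
      "multi-rater analogue on ordinally embedded labels.")
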