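#!/usr/bin/env python
"""Quantify DAB positivity on synthetic stained sections, markers anti-linked.

Generates HER2- and GLUT1-stained sections whose ground-truth positive
fractions are anti-correlated across subjects (high HER2 → low GLUT1), runs
the five-stage k-means positivity pipeline on each, and reports per-section
recovery error and the section-level HER2-vs-GLUT1 Spearman correlation.
Writes results/ihc_quant.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from petihc import cohort as ca, ihc, synthetic as syn

SEED = 1
N_SUBJECTS = 10
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(N_SUBJECTS):
        u = (i + 0.5) / N_SUBJECTS  # subject's HER2 rank position
        fracs = {"HER2": 0.10 + 0.55 * u + rng.normal(0, 0.03),
                 "GLUT1": 0.10 + 0.55 * (1 - u) + rng.normal(0, 0.03)}
        for marker, f in fracs.items():
            cfg = syn.SyntheticIHCConfig(positive_fraction=float(np.clip(f, 0, 1)),
                                         seed=int(rng.integers(2**31)))
            img, tissue, pos = syn.generate_ihc_image(cfg)
            truth = 100.0 * pos.sum() / tissue.sum()
            res = ihc.quantify_section(img, seed=SEED)
            rows.append({"subject": f"s{i:02d}", "marker": marker,
                         "true_percent": truth, **res.to_dict()})
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "ihc_quant.csv", index=False)

    err = (df["percent_positive"] - df["true_percent"]).abs()
    print(f"quantified {len(df)} sections; "
          f"recovery error mean {err.mean():.2f}, max {err.max():.2f} points")
    her2 = df[df["marker"] == "HER2"]["percent_positive"].to_numpy()
    glut1 = df[df["marker"] == "GLUT1"]["percent_positive"].to_numpy()
    r = ca.ihc_correlation(her2, glut1)
    print(f"HER2 vs GLUT1 percent positive: Spearman r = {r.estimate:.3f}, "
          f"p = {r.p_value:.4f} (n = {r.n})")


if __name__ == "__main__":
    main()
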