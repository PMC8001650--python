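#!/usr/bin/env python
"""Quantify SUV inside the phantom tumour ROIs and check against ground truth.

Regenerates the seeded phantom cohort, converts each activity volume to SUV,
summarizes mean/max/sum/SD and the frequency histogram under the ROI mask,
and reports how closely the recovered cohort means track the generating
distributions. Writes results/suv_summaries.csv.
"""

from pathlib import Path

import pandas as pd

from petihc import pet, synthetic as syn

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    subjects, _ = syn.generate_pet_cohort(syn.SyntheticPETConfig(seed=SEED))
    rows = []
    for ph in subjects:
        suv = pet.compute_suv(ph.volume)
        s = pet.summarize_roi(suv, ph.mask, bin_width=0.1)
        rows.append({"subject_id": ph.subject_id, "cohort": ph.cohort,
                     "true_mean": ph.true_mean, "suv_mean": s.mean,
                     "suv_max": s.max, "suv_sum": s.sum, "suv_sd": s.sd,
                     "n_voxels": s.n_voxels})
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "suv_summaries.csv", index=False)

    print(f"quantified {len(df)} tumours "
          f"({df['n_voxels'].iloc[0]} ROI voxels each)")
    for cohort, grp in df.groupby("cohort"):
        err = (grp["suv_mean"] - grp["true_mean"]).abs().max()
        print(f"  {cohort}: recovered SUV_mean {grp['suv_mean'].mean():.2f} "
              f"± {grp['suv_mean'].std(ddof=1):.2f}; "
              f"max |recovered − generating tumour mean| = {err:.3f}")


if __name__ == "__main__":
    main()
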