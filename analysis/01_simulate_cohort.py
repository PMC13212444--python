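#!/usr/bin/env python
"""Simulate the study cohort: mixed-gamble choices and covariates.

Generates the default synthetic cohort (22 AUD patients, 9 female; 19
behavioral controls, 8 female) with true loss aversion drawn from the
group distributions (AUD 1.90 +/- 0.23, HC 2.13 +/- 0.38), simulates a
104-trial mixed-gamble session per subject, and writes the subject and
choice tables under results/analysis/.
"""

from pathlib import Path

import numpy as np

from lapet import synthetic

OUT = Path("results/analysis")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    # same substream layout as lapet.pipeline.run_pipeline, so the cohort
    # here is the one the voxelwise scripts analyze
    ss = np.random.SeedSequence(SEED)
    gen = np.random.Generator(np.random.PCG64(ss.spawn(7)[0]))
    subjects, choices = synthetic.generate_cohort(seed=gen)

    subjects.to_csv(OUT / "subjects.tsv", sep="\t", index=False)
    choice_dir = OUT / "choices"
    choice_dir.mkdir(exist_ok=True)
    corrs = []
    for sid, tab in choices.items():
        tab.to_csv(choice_dir / f"{sid}.tsv", sep="\t", index=False)
        corrs.append(np.corrcoef(tab["gain"], tab["loss"])[0, 1])

    by_group = subjects.groupby("group")["true_lambda"].agg(["mean", "std",
                                                             "count"])
    print("cohort written to", OUT)
    print(by_group.round(3))
    print(f"max |gain-loss correlation| across designs: "
          f"{np.abs(corrs).max():.3f} (constraint: <= 0.10)")
    rates = [choices[s]["accept"].mean() for s in subjects["subject_id"]]
    print(f"acceptance rates: mean {np.mean(rates):.2f}, "
          f"range [{min(rates):.2f}, {max(rates):.2f}]")


if __name__ == "__main__":
    main()
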