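#!/usr/bin/env python
"""Sex-moderation of the loss-aversion / frontomedial-metabolism coupling.

Reads the pipeline report written by 03_voxelwise_metabolism.py (rerunning
it if absent) and prints the conditional-process moderation block for the
sex-by-LA interaction cluster ROI: robust-SE coefficient table, R-squared
change for the interaction, conditional effects per sex, bootstrap CIs,
Johnson-Neyman summary, and effect size / post-hoc power.
"""

import json
import subprocess
import sys
from pathlib import Path

REPORT = Path("results/run/report.json")


def main() -> None:
    if not REPORT.exists():
        subprocess.run(
            [sys.executable,
             Path(__file__).with_name("03_voxelwise_metabolism.py")],
            check=True)
    mod = json.loads(REPORT.read_text())["moderation"]

    print(f"model: R2 = {mod['r2']:.4f}, MSE = {mod['mse']:.4f}, "
          f"robust F({mod['df1']},{mod['df2']}) = {mod['f_robust']:.4f} "
          f"(classical F = {mod['f_classical']:.4f}), p = {mod['p_model']:.4f}")
    print("\ncoefficients (robust SEs):")
    for name, row in mod["coefficients"].items():
        print(f"  {name:12s} b = {row['coeff']:+.4f}  se = {row['se']:.4f}  "
              f"t = {row['t']:+.3f}  p = {row['p']:.4f}  "
              f"CI [{row['llci']:+.4f}, {row['ulci']:+.4f}]")
    print(f"\ninteraction: dR2 = {mod['delta_r2']:.4f}, robust "
          f"F(1,{mod['df2']}) = {mod['f_interaction_robust']:.4f}, "
          f"p = {mod['p_interaction_robust']:.4f}")
    print("\nconditional effects of ROI metabolism on loss aversion:")
    for ce in mod["conditional_effects"]:
        print(f"  sex = {ce['moderator_label']:6s} effect = "
              f"{ce['effect']:+.4f}  p = {ce['p']:.4f}  "
              f"CI [{ce['llci']:+.4f}, {ce['ulci']:+.4f}]")
    if "bootstrap" in mod:
        print(f"\nbootstrap (B = {mod['bootstrap_B']}):")
        for name, row in mod["bootstrap"].items():
            print(f"  {name:12s} mean = {row['boot_mean']:+.4f}  "
                  f"CI [{row['boot_llci']:+.4f}, {row['boot_ulci']:+.4f}]")
    es, pw = mod["effect_sizes"], mod["posthoc_power"]
    print(f"\neffect size: dR2 = {es['delta_r2']:.4f} -> Cohen's f2 = "
          f"{es['cohen_f2']:.4f}; post-hoc power = "
          f"{pw['power_ncp_n']:.3f} (ncp = f2*N) / "
          f"{pw['power_ncp_df']:.3f} (ncp = f2*(df1+df2+1))")
    print("Johnson-Neyman:", mod["johnson_neyman"]["region"])


if __name__ == "__main__":
    main()
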