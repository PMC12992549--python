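"""Drive efficiency on synthetic cross vials: pooled vs batch-aware rates.

Generates vial-level inheritance data under the measured conversion rates of
the two strongest drive lines, estimates the inheritance rate with both the
pooled binomial and the random-intercept GLMM, and contrasts male and female
drive parents with z-tests.  Writes results/drive_efficiency.csv.
"""

from pathlib import Path

import pandas as pd

from suppdrive.crosses import compare_rates_z, glmm_logit_rate, pooled_rate
from suppdrive.presets import get_preset
from suppdrive.synth import gen_cross_vials

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260919


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for preset_name in ("stl_cage1", "oct_nanos"):
        sc = get_preset(preset_name)
        line = preset_name.split("_")[0]
        ests = {}
        for sex in ("female", "male"):
            df = gen_cross_vials(
                20, SEED + hash(line + sex) % 10_000, dp=sc.dp,
                drive_parent_sex=sex, sigma_vial=0.5, mean_offspring=50,
            )
            vials = list(zip(df.n_carriers, df.n_offspring))
            pooled = pooled_rate(vials)
            glmm = glmm_logit_rate(vials)
            ests[sex] = glmm
            rows.append(
                {
                    "line": line, "drive_parent": sex,
                    "pooled_pct": 100 * pooled.estimate,
                    "pooled_se_pct": 100 * pooled.se,
                    "glmm_pct": 100 * glmm.estimate,
                    "glmm_se_pct": 100 * glmm.se,
                    "glmm_sigma": glmm.extras["sigma"],
                    "n_offspring": pooled.n,
                }
            )
        z, p = compare_rates_z(ests["female"], ests["male"])
        print(
            f"{line}: female {100 * ests['female'].estimate:.1f}% vs male "
            f"{100 * ests['male'].estimate:.1f}% inheritance (z={z:.2f}, p={p:.3f})"
        )
    out = pd.DataFrame(rows)
    out.to_csv(OUT / "drive_efficiency.csv", index=False)
    print(f"wrote {OUT / 'drive_efficiency.csv'}")


if __name__ == "__main__":
    main()
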