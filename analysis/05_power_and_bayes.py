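"""Desk statistics: prospective power for the paired designs and JZS Bayes
factors for the congruency contrasts found in step 04.

Prints the minimum detectable effect at n = 19, the sample size needed for
dz = 0.5 at 80% power, and the power of the pooled n = 53 sample against a
small (dz = 0.30) binding effect; then recomputes BF10 from the (t, n) pairs
of the step-04 duration-correlation tests as a from-t cross-check of the
BF values embedded in tests.json.
"""

import json
from pathlib import Path

from pinchbind.stats import PowerSpec, jzs_bf10, solve_power

ANALYSIS = Path("results/analysis")


def main() -> None:
    d = solve_power(PowerSpec(n=19, power=0.80, alpha=0.05)).d
    print(f"minimum detectable effect at n=19, power .80: dz = {d:.2f}")
    n = solve_power(PowerSpec(d=0.5, power=0.80, alpha=0.05)).n
    print(f"required n for dz = 0.5 at power .80: n = {n}")
    p = solve_power(PowerSpec(n=53, d=0.30, alpha=0.05)).power
    print(f"power of n=53 against dz = 0.30: {100 * p:.0f}%")

    for cohort in ("exp1", "exp2"):
        path = ANALYSIS / cohort / "tests.json"
        if not path.exists():
            print(f"(run analysis/04 first to get {path})")
            continue
        tests = json.loads(path.read_text())
        res = tests["duration_corr"]
        bf = jzs_bf10(res["t"], res["n"])
        print(f"{cohort} duration_corr: t({res['df']}) = {res['t']:+.2f} -> "
              f"BF10 from t = {bf:.3f} (pipeline value {res['bf10']:.3f})")


if __name__ == "__main__":
    main()
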