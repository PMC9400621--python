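"""Type-I-error calibration and power recovery of the congruency test.

Sweeps the retrieval-strength gap λ_congruent − λ_incongruent and reports the
rejection rate of the duration-correlation congruency test at each grid
point (feature-level simulation, 19 participants per dataset).  The null
cell (equal λ) checks that the test's false-positive rate sits at the
nominal 5%; the remaining cells trace the power curve of the design against
increasingly strong planted binding.  Table: results/recovery.csv.
"""

from pathlib import Path

from pinchbind.pipeline import recover

OUT = Path("results/recovery.csv")
GRID = [(0.55, 0.55), (0.60, 0.55), (0.65, 0.55), (0.75, 0.55), (0.90, 0.55)]


def main() -> None:
    table = recover(GRID, reps=1000, seed=20220606, n_participants=19)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT, index=False)
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.3f}"))
    null = table[table["lambda_c"] == table["lambda_i"]].iloc[0]
    print(f"\nnull rejection rate {null['rejection_rate']:.3f} "
          f"(MC SE {null['mc_se']:.3f}) vs nominal alpha .05")


if __name__ == "__main__":
    main()
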