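"""Simulate the two study cohorts and write their session files.

Generates a 19-participant session set with the sparse-catch design (7 blocks
of 30 trials, 20% catch) and a 34-participant set with the go-signal design
(9 blocks of 40 trials, 50% catch), using the default population parameters
and a moderate planted binding effect (λ congruent .65 vs incongruent .55).
Trial tables and metadata go to results/sim/<cohort>/; rendered force traces
are written for the first participant of each cohort only (they are bulky and
step 02 only needs a demonstration set — the analysis pipeline re-renders
traces in memory when asked).
"""

from pathlib import Path

from pinchbind import io as pio
from pinchbind.simulate import PopulationSpec, design_preset, generate_session

OUT = Path("results/sim")
SEED = 20220606
COHORTS = {"exp1": 19, "exp2": 34}


def main() -> None:
    for cohort, n in COHORTS.items():
        design = design_preset(cohort)
        pop = PopulationSpec(seed=SEED)
        out = OUT / cohort
        if (out / "trials.csv").exists():
            (out / "trials.csv").unlink()
        for i in range(n):
            render = i == 0
            records, traces = generate_session(
                design, pop, f"p{i + 1:02d}", participant_index=i,
                render_traces=render)
            pio.write_session(out, records, traces, design, pop,
                              write_traces=render)
        trials = pio.read_trials(out)
        print(f"{cohort}: {n} participants, {len(trials)} trials "
              f"({trials['condition'].value_counts().to_dict()}), "
              f"outcomes {trials['outcome'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
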