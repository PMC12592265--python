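"""Generate the two synthetic experiments the rest of the analysis consumes.

Experiment A (paired design): 15 control + 15 odour-test foragers, the
odour-effect profile (test ants meander more, walk slower, scan more and
mostly detour around the band).

Experiment B (repeated design): 16 subjects recorded in four conditions
(control, day1..day3 of repeated odour exposure), with habituation built
in: a strong shift on day 1 recovering toward control by day 3.

Writes trajectory CSVs plus ground-truth tables under results/simulated/.
"""

from pathlib import Path

from antnav import io, synthetic

SEED = 20240501
ROOT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    for name, design, profile, n in (
        ("exp1_odour", "paired", synthetic.ODOUR_EFFECT_PROFILE, 15),
        ("exp2_habituation", "repeated", synthetic.HABITUATION_PROFILE, 16),
    ):
        out = ROOT / name
        out.mkdir(parents=True, exist_ok=True)
        data, manifest = synthetic.simulate_experiment(design, profile, n, seed=SEED)
        for traj, _ in data:
            io.write_trajectory(traj, out / f"{traj.ant_id}.csv")
        manifest["file"] = [f"{t.ant_id}.csv" for t, _ in data]
        manifest.to_csv(out / "ground_truth.csv", index=False)
        print(f"{name}: {len(data)} trajectories ({design} design, seed {SEED}) -> {out}")


if __name__ == "__main__":
    main()
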