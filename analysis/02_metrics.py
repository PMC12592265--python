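"""Per-ant kinematic and straightness metrics for both synthetic experiments.

Reads the trajectory CSVs written by 01_simulate.py through the standard
reader, runs the full kinematics -> straightness -> scan-detection ->
route pipeline, and writes one tidy metrics table per experiment.
"""

from pathlib import Path

import pandas as pd

from antnav import ArenaGeometry, io, pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    arena = ArenaGeometry()
    for name in ("exp1_odour", "exp2_habituation"):
        src = ROOT / "simulated" / name
        manifest = pd.read_csv(src / "ground_truth.csv")
        trajs = []
        for _, row in manifest.iterrows():
            tr = io.read_trajectory(src / row["file"])
            trajs.append(tr.with_labels(ant_id=row["ant_id"], condition=row["condition"]))
        table = pipeline.summarise_batch(trajs, arena)
        out = ROOT / f"{name}_metrics.csv"
        io.write_metrics_table(table.to_dict("records"), out)
        print(f"{name}: {len(table)} ants -> {out}")
        print(
            table.groupby("condition")[["sinuosity", "mean_speed", "n_scan_bouts"]]
            .mean()
            .round(3)
            .to_string()
        )


if __name__ == "__main__":
    main()
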