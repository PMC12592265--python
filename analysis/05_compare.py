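"""Statistics layer over the per-ant metrics tables.

Experiment A: one Welch (unequal-variance) t-test per metric, control vs
odour-test. Experiment B: one-way within-subject ANOVA per metric over
(control, day1, day2, day3) with the three a priori Helmert contrasts
(control vs test days; day1 vs days 2-3; day2 vs day3).
"""

from pathlib import Path

import numpy as np

from antnav import batch_compare, io, rm_anova

ROOT = Path(__file__).resolve().parent.parent / "results"
METRICS = ["sinuosity", "e_a_max", "mean_speed", "mean_abs_angular_velocity",
           "duration", "n_scan_bouts", "mean_scan_duration"]
CONDITIONS = ["control", "day1", "day2", "day3"]


def main() -> None:
    exp1 = io.read_metrics_table(ROOT / "exp1_odour_metrics.csv")
    ctrl = exp1[exp1.condition == "control"]
    test = exp1[exp1.condition == "test"]
    report = batch_compare(ctrl, test, METRICS)
    out = ROOT / "exp1_odour_comparisons.csv"
    report.to_csv(out, index=False, float_format="%.17g")
    print(f"Experiment A (control vs test, Welch t per metric) -> {out}")
    for _, r in report.iterrows():
        print(
            f"  {r['metric']}: t = {r['t']:.1f}, df = {r['df']:.1f}, p = {r['p']:.2g} "
            f"({r['mean_control']:.3g} vs {r['mean_test']:.3g})"
        )

    exp2 = io.read_metrics_table(ROOT / "exp2_habituation_metrics.csv")
    print("\nExperiment B (repeated measures, Helmert contrasts):")
    anova_rows = []
    for metric in METRICS:
        wide = np.column_stack(
            [
                exp2[exp2.condition == c].sort_values("ant_id")[metric].to_numpy()
                for c in CONDITIONS
            ]
        )
        res = rm_anova(wide, CONDITIONS)
        print(f"  {metric}: F({res.df_num:g},{res.df_den:g}) = {res.F:.1f}, p = {res.p:.2g}")
        for c in res.contrasts:
            print(f"    {c.label}: estimate {c.estimate:.3g}, t = {c.t:.1f}, p = {c.p:.2g}")
            anova_rows.append(
                {"metric": metric, "F": res.F, "p_anova": res.p, "contrast": c.label,
                 "estimate": c.estimate, "t": c.t, "df": c.df, "p": c.p, "z": c.z}
            )
    import pandas as pd

    out2 = ROOT / "exp2_habituation_anova.csv"
    pd.DataFrame(anova_rows).to_csv(out2, index=False, float_format="%.17g")
    print(f"-> {out2}")


if __name__ == "__main__":
    main()
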