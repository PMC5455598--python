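"""Adjusted effect estimates: continuous models and per-count series.

Fits the stage-migration logistic model and the overall-survival Cox
models with ELN count continuous (the headline per-node OR/HR), tests
histology interactions, and builds the per-ELN-count effect series
(reference: one examined node) that feed the break-point scan.
"""

import argparse
import json
from pathlib import Path

from elncut import (eln_effect_series, fit_stage_migration, fit_survival_model,
                    interaction_test, mean_positive_series,
                    positive_vs_examined_regression, read_cohort)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--sparsity-floor", type=int, default=20)
    args = ap.parse_args()

    cohort = read_cohort(args.results / "cohorts" / "derivation.csv")

    def show(label, ratio):
        print(f"  {label}: {ratio['estimate']:.3f} "
              f"(95% CI {ratio['ci_low']:.3f}-{ratio['ci_high']:.3f}, "
              f"p={ratio['p_value']:.2g})")

    print("per-examined-node adjusted effects (ELN continuous):")
    migration = fit_stage_migration(cohort)
    show("stage-migration OR", migration.ratio("eln_count"))
    hr_n0 = fit_survival_model(cohort, subset="node-negative")
    show("OS HR, node-negative", hr_n0.ratio("eln_count"))
    hr_np = fit_survival_model(cohort, subset="node-positive")
    show("OS HR, node-positive", hr_np.ratio("eln_count"))
    hr_np2 = fit_survival_model(cohort, subset="node-positive",
                                include_positive_count=True)
    show("OS HR, node-positive (+ positive count)", hr_np2.ratio("eln_count"))
    hr_n2 = fit_survival_model(cohort, subset="N2-only")
    show("OS HR, N2 only", hr_n2.ratio("eln_count"))

    slope, r2 = positive_vs_examined_regression(cohort)
    slope_p, r2_p = positive_vs_examined_regression(cohort, subset="node-positive")
    print(f"  mean positives vs ELN: slope {slope:.3f}, R^2 {r2:.3f} "
          f"(node-positive subset R^2 {r2_p:.3f})")

    p_mig = interaction_test(cohort, outcome="stage-migration")
    p_os = interaction_test(cohort, outcome="survival")
    print(f"  histology x ELN interaction: migration p={p_mig:.2f}, OS p={p_os:.2f}")

    or_series = eln_effect_series(cohort, outcome="stage-migration",
                                  sparsity_floor=args.sparsity_floor)
    hr_series = eln_effect_series(cohort, outcome="survival", subset="node-negative",
                                  sparsity_floor=args.sparsity_floor)
    mp_series = mean_positive_series(cohort, sparsity_floor=args.sparsity_floor,
                                     terminal_percentile=99.0)
    for name, table in (("migration", or_series.table), ("survival", hr_series.table),
                        ("mean_positive", mp_series)):
        out = args.results / f"series_{name}.tsv"
        table.to_csv(out, sep="\t", index=False)
        print(f"  wrote {len(table)}-level {name} series to {out}")

    (args.results / "continuous_models.json").write_text(json.dumps({
        "stage_migration_or": migration.ratio("eln_count"),
        "os_hr_node_negative": hr_n0.ratio("eln_count"),
        "os_hr_node_positive": hr_np.ratio("eln_count"),
        "os_hr_node_positive_with_positive_count": hr_np2.ratio("eln_count"),
        "os_hr_n2_only": hr_n2.ratio("eln_count"),
        "positive_vs_examined": {"slope": slope, "r_squared": r2},
        "interaction_p": {"migration": p_mig, "survival": p_os},
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
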