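"""Cut-point validation: dichotomized hazard ratios and adjusted curves.

Evaluates the selected examined-node threshold on the node-negative
subsets of the derivation, independent validation and high-yield
cohorts: adjusted Cox HR (at-or-above vs below threshold) and
covariate-adjusted survival curves.
"""

import argparse
import json
from pathlib import Path

from elncut import adjusted_survival_curves, dichotomize_and_fit, read_cohort, validate_on_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--threshold", type=int, default=None,
                    help="override the cut point selected in step 04")
    args = ap.parse_args()

    if args.threshold is None:
        cut = json.loads((args.results / "cutpoint.json").read_text())
        threshold = int(round(cut["cutpoint"]))
    else:
        threshold = args.threshold
    print(f"evaluating threshold of {threshold} examined nodes "
          "(declared node-negative disease):")

    derivation = read_cohort(args.results / "cohorts" / "derivation.csv")
    fits = {"derivation": dichotomize_and_fit(derivation, threshold=threshold)}
    for name in ("validation", "high_yield"):
        cohort = read_cohort(args.results / "cohorts" / f"{name}.csv")
        fits[name] = validate_on_cohort(cohort, threshold=threshold)
    for name, fit in fits.items():
        print(f"  {name}: HR {fit.hr:.3f} (95% CI {fit.ci[0]:.3f}-{fit.ci[1]:.3f}, "
              f"p={fit.p_value:.2g}; {fit.n_above} at/above vs {fit.n_below} below)")

    curves = adjusted_survival_curves(derivation, threshold=threshold)
    out = args.results / "adjusted_curves.tsv"
    curves.to_csv(out, sep="\t", index=False)
    print(f"\nadjusted survival curves (reference covariate profile) written to {out}")
    (args.results / "cutpoint_validation.json").write_text(json.dumps(
        {name: fit.as_dict() for name, fit in fits.items()}, indent=2) + "\n")


if __name__ == "__main__":
    main()
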