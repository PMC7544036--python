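"""Evaluate the fitted signature's stratification of the training cohort.

Kaplan-Meier / log-rank between risk groups, restricted mean survival,
univariate and multivariate Cox tables over the clinical covariates, and
mutation-stratified subgroup analyses. Writes tidy tables under
results/evaluation/.
"""

import json
import pathlib

from irgps import read_clinical, read_expression, read_signature
from irgps.pipeline import RunConfig, score_workflow

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
SCRATCH = pathlib.Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    out = BASE / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    expression = read_expression(str(SCRATCH / "cohorts" / "training_expression.tsv"))
    clinical = read_clinical(str(SCRATCH / "cohorts" / "training_clinical.tsv"))
    signature = read_signature(str(BASE / "fit" / "fitted_signature.json"))

    result = score_workflow(expression, clinical, signature, RunConfig())
    result.scores.to_frame().join(result.groups).to_csv(out / "risk_scores.tsv", sep="\t")
    result.cox_table.to_csv(out / "cox_table.tsv", sep="\t", index=False)

    n_high = int((result.groups == "high").sum())
    print(f"risk groups: {n_high} high / {len(result.groups) - n_high} low")
    print(f"log-rank: chi2 = {result.logrank.statistic:.2f}, p = {result.logrank.p:.3g}")
    print(f"restricted mean survival (tau {result.rmst['tau']:.0f} mo): "
          f"high {result.rmst['rmst']['high']:.1f} vs low {result.rmst['rmst']['low']:.1f} "
          f"(ratio {result.rmst['ratio']:.2f})")
    risk_rows = result.cox_table[result.cox_table["variable"] == "risk_score"]
    for _, row in risk_rows.iterrows():
        print(f"Cox {row['analysis']}: HR {row['hazard_ratio']:.3f} "
              f"({row['ci_low']:.3f}-{row['ci_high']:.3f}), p = {row['wald_p']:.3g}")
    summary = {
        "logrank_p": result.logrank.p,
        "rmst": result.rmst,
        "mutation_score_tests": result.mutation_score_tests,
        "subgroup_logrank_p": {
            flag: {str(k): (v["logrank"].p if v["logrank"] else None) for k, v in strata.items()}
            for flag, strata in result.subgroups.items()
        },
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, default=str)
    for flag, strata in summary["subgroup_logrank_p"].items():
        print(f"subgroups by {flag}: log-rank p per stratum {strata}")


if __name__ == "__main__":
    main()
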