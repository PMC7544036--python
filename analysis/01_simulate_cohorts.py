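"""Generate the study cohorts: a training cohort and a distorted replica.

Writes a 300-patient, 100-gene synthetic melanoma-like cohort (expression
TSV + clinical TSV + ground-truth JSON) under scratch/cohorts/ — bulky
intermediate data, not a result — plus a "cross-platform" replica of the
same patients whose expression has been pushed through per-sample
monotone distortions: the raw material for the normalization-free claim
tested in 03.
"""

import json
import pathlib

import numpy as np

from irgps import SimulationConfig, apply_platform_distortion, simulate_cohort, write_expression

OUT = pathlib.Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    expression, clinical, truth = simulate_cohort(config)
    write_expression(expression, OUT / "training_expression.tsv")
    clinical.to_csv(OUT / "training_clinical.tsv", sep="\t")
    distorted = apply_platform_distortion(expression, "power", seed=SEED + 1)
    write_expression(distorted, OUT / "training_expression_otherplatform.tsv")
    with open(OUT / "truth.json", "w") as handle:
        json.dump(
            {
                "true_pairs": truth["true_pairs"],
                "betas": truth["betas"],
                "realized_censoring": truth["realized_censoring"],
                "seed": SEED,
            },
            handle,
            indent=2,
        )
    print(f"cohort: {expression.shape[1]} patients x {expression.shape[0]} genes")
    print(f"events: {int(clinical['event'].sum())} "
          f"(censoring {truth['realized_censoring']:.1%}, target {config.censoring_fraction:.0%})")
    print(f"prognostic pairs: {truth['true_pairs']} with log-HRs {truth['betas']}")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
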