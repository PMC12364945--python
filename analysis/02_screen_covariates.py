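"""Severity regression and covariate screening on the simulated cohort.

Regresses total symptom severity (sum of the 18 ratings) on the
covariates, reports B, standardized beta, p, 95% CI and VIF per
predictor, screens at the stringent alpha = 0.001, and computes the
post hoc power of the overall F test for a 13-predictor model at a
medium effect size (f^2 = 0.15, alpha = 0.001, N = 324).
"""

from pathlib import Path

import symptomnet as sn

OUT = Path(__file__).resolve().parents[1] / "results"
ALPHA_SCREEN = 0.001

COVARIATE_SPEC = {
    "active_stage": "binary",
    "years_since_diagnosis": "continuous",
    "treatment_surgery": "binary",
    "treatment_both": "binary",
    "treatment_otherwise": "binary",
}


def main() -> None:
    table = sn.read_symptom_table(
        OUT / "cohort.csv", item_columns=sn.SCS_IBD_ITEMS,
        covariate_spec=COVARIATE_SPEC,
    )
    report = sn.fit_severity_model(table)
    report.coef_table.round(4).to_csv(OUT / "severity_regression.csv")
    selected = sn.screen_covariates(report, ALPHA_SCREEN)
    (OUT / "selected_covariates.txt").write_text("\n".join(selected) + "\n")

    print(f"severity model R^2 = {report.r_squared:.3f} "
          f"(n={report.diagnostics['n_obs']})")
    print(report.coef_table.round(3).to_string())
    print(f"diagnostics: max VIF {report.diagnostics['max_vif']:.2f}, "
          f"heteroscedasticity flag {report.diagnostics['heteroscedasticity_flag']}, "
          f"non-normal residuals flag {report.diagnostics['non_normal_residuals_flag']}")
    print(f"selected at p < {ALPHA_SCREEN}: {selected}")

    power = sn.power_f_test(sn.PowerSpec(u=13, f2=0.15, alpha=0.001, N=324))
    print(f"post hoc power (u=13, f^2=0.15, alpha=0.001, N=324): {power:.4f}")


if __name__ == "__main__":
    main()
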