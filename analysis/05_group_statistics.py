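"""Inferential layer: adjusted group comparisons and clinical correlations.

ANCOVA (age/sex/education adjusted) across the cognitive panel and the
battery composites with BH-FDR within the family; the sex 2x2 chi-square;
and, among patients, partial correlations between the FDR-significant
cognitive scores and the clinical chemistry (PBG, FBG, GLU, MAlb,
disease duration) as a second FDR family.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from t2ebm.stats import chi_square_2x2, compare_family, correlation_family

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stats"
CLINICAL = ["PBG", "FBG", "GLU", "MAlb", "duration"]


def main() -> None:
    cov = pd.read_csv(ROOT / "cohort" / "covariates.csv")
    bio = pd.read_csv(ROOT / "cohort" / "biomarkers.csv")
    scores = pd.read_csv(ROOT / "pca" / "battery_scores.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    group = cov["group"].to_numpy()
    covars = cov[["age", "sex", "education"]]

    sex_table = np.array(
        [[(cov["sex"][group == g] == 1).sum(), (cov["sex"][group == g] == 0).sum()]
         for g in ("patient", "control")])
    chi2, _, p_chi = chi_square_2x2(sex_table)
    print(f"sex distribution chi2 = {chi2:.3f} (p = {p_chi:.3f})")

    # observed outcomes: the directly measured scales plus the PCA-recovered
    # battery scores (the generator's latent PC columns are not observables)
    raw = ["MMSE", "MoCA", "TMT_A", "TMT_B", "SAS", "SDS"]
    outcomes = pd.concat(
        [bio[raw], scores.drop(columns="id")], axis=1)
    comparisons = compare_family(outcomes, group, covars)
    comp_df = pd.DataFrame(
        [{"variable": r.variable, "F": round(r.statistic, 3),
          "p": r.p_value, "p_fdr": r.p_fdr,
          **{f"adj_mean_{k}": round(v, 3) for k, v in r.adjusted_means.items()}}
         for r in comparisons]).sort_values("p_fdr")
    comp_df.to_csv(OUT / "group_comparisons.csv", index=False)
    sig = comp_df.loc[comp_df["p_fdr"] < 0.05, "variable"].tolist()
    print(f"{len(sig)}/{len(comp_df)} outcomes differ between groups after FDR:")
    for v in sig[:10]:
        row = comp_df[comp_df["variable"] == v].iloc[0]
        print(f"  {v:<12s} F={row['F']:.1f}  p_fdr={row['p_fdr']:.4f}")

    pat = group == "patient"
    if sig:
        corr = correlation_family(outcomes.loc[pat, sig],
                                  cov.loc[pat, CLINICAL], covars.loc[pat])
        corr_df = pd.DataFrame(
            [{"score": r.x, "clinical": r.y, "r": round(r.r, 3),
              "p": r.p_value, "p_fdr": r.p_fdr} for r in corr]
        ).sort_values("p_fdr")
        corr_df.to_csv(OUT / "partial_correlations.csv", index=False)
        top = corr_df.iloc[0]
        print(f"strongest adjusted correlation among patients: "
              f"{top['score']} x {top['clinical']}: r = {top['r']:.3f} "
              f"(p_fdr = {top['p_fdr']:.3f})")
        n_sig = int((corr_df["p_fdr"] < 0.05).sum())
        print(f"{n_sig} correlation(s) survive FDR within the family "
              f"of {len(corr_df)}")


if __name__ == "__main__":
    main()
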