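"""Reduce the item-level batteries to principal-component scores.

For each battery the items are z-scored against the healthy controls,
checked for sampling adequacy (KMO, Bartlett's sphericity), decomposed on
the correlation matrix, and reduced to the Kaiser-selected components plus
an explained-variance-weighted composite.  Outputs go to results/pca/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from t2ebm.pca import reduce_battery

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "pca"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    cov = pd.read_csv(cohort_dir / "covariates.csv")
    control_mask = (cov["group"] == "control").to_numpy()
    OUT.mkdir(parents=True, exist_ok=True)

    tables, report = [], {}
    for f in sorted(cohort_dir.glob("items_*.csv")):
        name = f.stem.removeprefix("items_")
        items = pd.read_csv(f).drop(columns="id")
        scores, model, adequacy = reduce_battery(items, control_mask, name)
        tables.append(scores)
        report[name] = {
            "n_items": items.shape[1],
            "kmo": round(adequacy.kmo_overall, 3),
            "bartlett_chi2": round(adequacy.bartlett_chi2, 1),
            "bartlett_p": adequacy.bartlett_p,
            "eigenvalues_gt1": [round(float(e), 2) for e in model.eigenvalues
                                if e > 1.0],
            "n_selected": model.n_selected,
            "cum_explained_pct": round(
                100 * model.explained_fraction[:model.n_selected].sum(), 2),
        }
        print(f"{name}: KMO={report[name]['kmo']}, "
              f"Bartlett chi2={report[name]['bartlett_chi2']} "
              f"(p={adequacy.bartlett_p:.2e}), "
              f"{model.n_selected} components kept "
              f"({report[name]['cum_explained_pct']}% of variance), "
              f"eigenvalues {report[name]['eigenvalues_gt1']}")

    all_scores = pd.concat(tables, axis=1)
    all_scores.insert(0, "id", cov["id"])
    all_scores.to_csv(OUT / "battery_scores.csv", index=False)
    with open(OUT / "pca_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"scores for {all_scores.shape[0]} subjects written to {OUT}")


if __name__ == "__main__":
    main()
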