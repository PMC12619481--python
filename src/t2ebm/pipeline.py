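"""End-to-end pipeline: simulate/load -> preprocess -> PCA -> EBM -> staging -> stats.

The runner is deterministic given its config and seed: one root
``SeedSequence`` spawns named substreams per stage, so e.g. changing the
bootstrap count does not perturb the simulated cohort.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ebm import fit_ebm, bootstrap_sequence, quantize_severity
from .pca import reduce_battery
from .preprocess import prepare_biomarkers
from .staging import em_refine
from .stats import (
    chi_square_2x2,
    compare_family,
    correlation_family,
    two_sample_t,
)
from .synthetic import CohortSpec, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

RAW_MARKERS = ("MMSE", "MoCA", "TMT_A", "TMT_B", "SAS", "SDS")
CLINICAL_VARS = ("PBG", "FBG", "GLU", "MAlb", "duration")


@dataclass
class PipelineConfig:
    """Everything a run needs; read from YAML, overridable by CLI flags."""

    data_dir: str | None = None       # cohort CSVs; None -> simulate
    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    n_patients: int = 119
    n_controls: int = 87
    bootstrap_B: int = 100
    em_restarts: int = 5
    composite_weighting: str = "eigenvalue"
    include_mood_scales: bool = True  # SAS/SDS as events
    run_gmv: bool = True              # fit the 35-ROI GMV EBM when gmv.csv exists
    gmv_bootstrap_B: int = 0          # 0 skips the (heavy) GMV bootstrap
    tiv_correction: bool = True       # divide GMV by total intracranial volume
    figures: bool = False

    def validate(self) -> None:
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if not self.simulate and self.data_dir is None:
            raise ValueError("data_dir required when simulate is false")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _log(msg: str) -> None:
    print(f"[t2ebm {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _load_cohort_dir(data_dir: Path):
    cov = pd.read_csv(data_dir / "covariates.csv")
    bio = pd.read_csv(data_dir / "biomarkers.csv")
    items = {}
    for f in sorted(data_dir.glob("items_*.csv")):
        items[f.stem.removeprefix("items_")] = pd.read_csv(f)
    manifest_path = data_dir / "biomarker_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"biomarker manifest not found: {manifest_path} "
            "(direction flags are required before EBM fitting)"
        )
    with open(manifest_path) as fh:
        directions = json.load(fh)["higher_is_worse"]
    return cov, bio, items, directions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict written to disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    ss_sim, ss_ebm, ss_boot = root.spawn(3)

    if config.simulate:
        _log(f"simulating cohort (seed={config.seed})")
        spec = CohortSpec(
            n_patients=config.n_patients, n_controls=config.n_controls,
            seed=ss_sim.generate_state(1)[0] % (2**31),
        )
        cohort, truth = generate_cohort(spec)
        data_dir = out / "data"
        write_cohort(cohort, truth, data_dir)
    else:
        data_dir = Path(config.data_dir)
    cov, bio, items, directions = _load_cohort_dir(data_dir)

    group = cov["group"].to_numpy()
    control_mask = group == "control"
    covariates = cov[["age", "sex", "education"]]

    # --- PCA reduction of the item-level batteries -------------------------
    _log("reducing batteries by PCA")
    score_tables, pca_reports = [], {}
    for name, df in items.items():
        scores, model, report = reduce_battery(
            df.drop(columns="id"), control_mask, name
        )
        score_tables.append(scores)
        pca_reports[name] = {
            "kmo": report.kmo_overall,
            "bartlett_chi2": report.bartlett_chi2,
            "bartlett_p": report.bartlett_p,
            "eigenvalues": model.eigenvalues.tolist(),
            "n_selected": model.n_selected,
            "explained_pct": (100 * model.explained_fraction).tolist(),
        }
    pc_scores = pd.concat(score_tables, axis=1)
    pc_scores.to_csv(out / "battery_scores.csv", index=False)
    with open(out / "pca_report.json", "w") as fh:
        json.dump(pca_reports, fh, indent=2)

    # --- assemble and preprocess the cognitive panel -----------------------
    panel_cols = [c for c in RAW_MARKERS if c in bio.columns]
    if not config.include_mood_scales:
        panel_cols = [c for c in panel_cols if c not in ("SAS", "SDS")]
    panel = pd.concat(
        [bio[panel_cols],
         pc_scores[[c for c in pc_scores.columns if not c.endswith("_PC")]]],
        axis=1,
    )
    flags = {c: directions[c] for c in panel_cols}
    flags |= {c: False for c in panel.columns if c not in flags}  # PC scores: higher=better
    prepared = prepare_biomarkers(panel, covariates, flags, control_mask)
    prepared.to_csv(out / "prepared_biomarkers.csv", index=False)

    # --- event-based model --------------------------------------------------
    _log(f"fitting EBM on {prepared.shape[1]} biomarkers")
    rng_ebm = np.random.default_rng(ss_ebm)
    X = prepared.to_numpy()
    ebm = fit_ebm(X, control_mask, list(prepared.columns), rng=rng_ebm,
                  n_restarts=config.em_restarts)
    seq_df = pd.DataFrame(
        {
            "position": np.arange(len(ebm.sequence.ordering)),
            "biomarker": [prepared.columns[i] for i in ebm.sequence.ordering],
            "event_center": ebm.sequence.event_centers,
        }
    )
    seq_df.to_csv(out / "sequence.csv", index=False)
    sev = pd.DataFrame(quantize_severity(ebm.posteriors), columns=prepared.columns)
    sev.insert(0, "id", bio["id"])
    sev.to_csv(out / "severity_levels.csv", index=False)

    _log(f"bootstrap (B={config.bootstrap_B})")
    rng_boot = np.random.default_rng(ss_boot)
    F, ec_samples = bootstrap_sequence(
        X, control_mask, B=config.bootstrap_B, rng=rng_boot,
        n_restarts=config.em_restarts, init_ordering=ebm.sequence.ordering,
    )
    pd.DataFrame(F, index=prepared.columns).to_csv(out / "positional_variance.csv")

    # --- staging ------------------------------------------------------------
    _log("staging subjects")
    staging = em_refine(X, ebm.sequence, ebm.fits)
    stage_df = staging.assignments.copy()
    stage_df.insert(0, "id", bio["id"])
    stage_df.insert(1, "group", group)
    stage_df.to_csv(out / "stages.csv", index=False)

    # --- statistics ---------------------------------------------------------
    _log("group statistics")
    pat_stage = stage_df.loc[group == "patient", "normalized_stage"]
    ctl_stage = stage_df.loc[group == "control", "normalized_stage"]
    t, df_t, p_t = two_sample_t(pat_stage, ctl_stage)
    sex_table = np.array(
        [
            [(cov["sex"][group == g] == 1).sum(), (cov["sex"][group == g] == 0).sum()]
            for g in ("patient", "control")
        ]
    )
    chi2, _, p_chi = chi_square_2x2(sex_table)

    outcome_cols = list(panel.columns) + [
        c for c in pc_scores.columns if c.endswith("_PC")
    ]
    outcomes = pd.concat([panel, pc_scores[[c for c in pc_scores.columns
                                            if c.endswith("_PC")]]], axis=1)
    comparisons = compare_family(outcomes[outcome_cols], group, covariates)
    comp_df = pd.DataFrame(
        [
            {"variable": r.variable, "F": r.statistic, "p": r.p_value,
             "p_fdr": r.p_fdr, **{f"mean_{k}": v for k, v in r.adjusted_means.items()}}
            for r in comparisons
        ]
    )
    comp_df.to_csv(out / "group_comparisons.csv", index=False)

    significant = [r.variable for r in comparisons
                   if r.p_fdr is not None and r.p_fdr < 0.05]
    pat = group == "patient"
    clin_cols = [c for c in CLINICAL_VARS if c in cov.columns]
    corr_results = []
    if significant and clin_cols:
        corr_results = correlation_family(
            outcomes.loc[pat, significant],
            cov.loc[pat, clin_cols],
            covariates.loc[pat],
        )
        pd.DataFrame(
            [{"score": r.x, "clinical": r.y, "r": r.r, "p": r.p_value,
              "p_fdr": r.p_fdr} for r in corr_results]
        ).to_csv(out / "partial_correlations.csv", index=False)

    # --- GMV event-based model (independent of the cognitive panel) --------
    gmv_summary = {}
    gmv_path = data_dir / "gmv.csv"
    if config.run_gmv and gmv_path.exists():
        _log("fitting GMV EBM (35 ROI features)")
        from .preprocess import aggregate_rois

        gmv_raw = pd.read_csv(gmv_path)
        tiv = gmv_raw.pop("TIV")
        rois = aggregate_rois(gmv_raw.drop(columns="id"))
        gmv_flags = {c: False for c in rois.columns}   # more volume = better
        gmv_prep = prepare_biomarkers(
            rois, covariates, gmv_flags, control_mask,
            tiv=tiv if config.tiv_correction else None,
        )
        rng_gmv = np.random.default_rng(root.spawn(1)[0])
        Xg = gmv_prep.to_numpy()
        gmv_ebm = fit_ebm(Xg, control_mask, list(gmv_prep.columns), rng=rng_gmv,
                          n_restarts=config.em_restarts)
        pd.DataFrame(
            {
                "position": np.arange(len(gmv_ebm.sequence.ordering)),
                "feature": [gmv_prep.columns[i] for i in gmv_ebm.sequence.ordering],
                "event_center": gmv_ebm.sequence.event_centers,
            }
        ).to_csv(out / "sequence_gmv.csv", index=False)
        gmv_staging = em_refine(Xg, gmv_ebm.sequence, gmv_ebm.fits)
        gmv_stage_df = gmv_staging.assignments.copy()
        gmv_stage_df.insert(0, "id", bio["id"])
        gmv_stage_df.insert(1, "group", group)
        gmv_stage_df.to_csv(out / "stages_gmv.csv", index=False)
        pat_g = gmv_stage_df.loc[group == "patient", "normalized_stage"]
        ctl_g = gmv_stage_df.loc[group == "control", "normalized_stage"]
        tg, dfg, pg = two_sample_t(pat_g, ctl_g)
        gmv_summary = {
            "gmv_stage_patient_mean": float(pat_g.mean()),
            "gmv_stage_control_mean": float(ctl_g.mean()),
            "gmv_stage_t": tg, "gmv_stage_p": pg,
            "gmv_first_feature": str(gmv_prep.columns[gmv_ebm.sequence.ordering[0]]),
        }
        if config.gmv_bootstrap_B >= 1:
            Fg, _ = bootstrap_sequence(
                Xg, control_mask, B=config.gmv_bootstrap_B, rng=rng_gmv,
                n_restarts=config.em_restarts,
                init_ordering=gmv_ebm.sequence.ordering,
            )
            pd.DataFrame(Fg, index=gmv_prep.columns).to_csv(
                out / "positional_variance_gmv.csv")

    if config.figures:
        _plot_positional_variance(F, list(prepared.columns), out / "positional_variance.png")

    summary = {
        "stage_patient_mean": float(pat_stage.mean()),
        "stage_patient_sd": float(pat_stage.std(ddof=1)),
        "stage_control_mean": float(ctl_stage.mean()),
        "stage_control_sd": float(ctl_stage.std(ddof=1)),
        "stage_t": t, "stage_df": df_t, "stage_p": p_t,
        "sex_chi2": chi2, "sex_chi2_p": p_chi,
        "n_significant_comparisons": len(significant),
        "sequence": seq_df["biomarker"].tolist(),
        "event_centers": seq_df["event_center"].tolist(),
        **gmv_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    _log("done")
    return summary


def _plot_positional_variance(F: np.ndarray, names: list[str], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    order = np.argsort(np.argmax(F, axis=1))
    ax.imshow(F[order], cmap="Blues", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(names)), [names[i] for i in order], fontsize=7)
    ax.set_xlabel("sequence position")
    ax.set_title("Positional variance (bootstrap frequency)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
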