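"""Synthetic cohorts with a known ground-truth event sequence.

The generator emulates a two-group cross-sectional study (patients and
healthy controls) in which each subject sits at a latent disease stage
``k``: the first ``k`` biomarkers of a ground-truth event sequence have
transitioned from their "normal" to their "abnormal" distribution, the
rest have not.  Item-level neuropsychological battery scores are produced
from a latent-factor structure so that the PCA stage has something real
to recover, and linear age/sex/education confounds are added so the
covariate-adjustment stage is exercised.

Because every subject's stage and the true ordering are returned alongside
the data, every downstream stage of the pipeline (mixture fitting, sequence
estimation, staging, statistics) can be validated against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BatterySpec",
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "battery_presets",
    "default_directions",
    "generate_cohort",
    "generate_battery_items",
    "write_cohort",
    "DEFAULT_COGNITIVE_PANEL",
]

#: Biomarker panel of the cognitive event-based model: global screens,
#: timed attention tests, mood scales and the per-battery principal
#: component scores.
DEFAULT_COGNITIVE_PANEL = (
    "MMSE", "MoCA", "TMT_A", "TMT_B", "SAS", "SDS",
    "CVLT_PC1", "CVLT_PC2", "CVLT_PC3", "CVLT_PC4",
    "STROOP_PC1", "STROOP_PC2",
    "WCST_PC1", "WCST_PC2", "WCST_PC3", "WCST_PC4",
)


def _load_manifest(name: str) -> dict:
    with resources.files("t2ebm.manifests").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class BatterySpec:
    """Latent-factor layout of one neuropsychological battery.

    Each item loads on exactly one factor; item score = loading * factor
    score + Gaussian noise.
    """

    name: str
    items: list[str]
    factor_of_item: list[int]          # factor index per item
    n_factors: int
    loading: float = 0.8
    noise_sd: float = 0.6

    def validate(self) -> None:
        if len(self.items) < self.n_factors or self.n_factors < 1:
            raise ValueError(
                f"battery {self.name}: need n_items >= n_factors >= 1, "
                f"got {len(self.items)} items / {self.n_factors} factors"
            )
        if self.noise_sd < 0:
            raise ValueError(f"battery {self.name}: noise_sd must be >= 0")
        counts = np.bincount(self.factor_of_item, minlength=self.n_factors)
        if (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(
                f"battery {self.name}: factor {empty} loads on no item"
            )


def battery_presets(loading: float = 0.8, noise_sd: float = 0.6) -> list[BatterySpec]:
    """Battery layouts shipped with the package (CVLT 17/4, STROOP 11/2, WCST 15/4)."""
    manifest = _load_manifest("batteries.json")
    specs = []
    for name, entry in manifest.items():
        if name.startswith("_"):
            continue
        items: list[str] = []
        factor_of_item: list[int] = []
        for f_idx, members in enumerate(entry["factors"].values()):
            items.extend(members)
            factor_of_item.extend([f_idx] * len(members))
        specs.append(
            BatterySpec(
                name=name,
                items=items,
                factor_of_item=factor_of_item,
                n_factors=len(entry["factors"]),
                loading=loading,
                noise_sd=noise_sd,
            )
        )
    return specs


def default_directions() -> dict[str, bool]:
    """Direction flags (higher_is_worse) for the default cognitive panel."""
    manifest = _load_manifest("biomarkers.json")
    return {k: v["higher_is_worse"] for k, v in manifest["cognitive_panel"].items()}


# Group-specific clinical chemistry (mean, sd) used only to exercise the
# correlation stage: FBG/PBG/GLU in mmol/L, HbA1c in %, MAlb in mg/L,
# duration in years.
_CLINICAL_PARAMS = {
    "FBG": ((7.942, 2.910), (3.972, 2.436)),
    "PBG": ((10.977, 4.186), (7.320, 0.910)),
    "GLU": ((8.503, 2.848), (5.978, 1.025)),
    "HbA1c": ((8.575, 2.060), (5.561, 0.297)),
    "MAlb": ((79.703, 151.511), (17.420, 11.797)),
    "duration": ((9.632, 7.037), (0.0, 0.0)),
}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study conditions: 119 patients vs 87 controls,
    a 16-marker cognitive panel with a 2-sd normal/abnormal separation,
    and overlapping binomial stage distributions (p=0.55 patients vs 0.45
    controls) so controls sit at nonzero but stochastically smaller stages.
    """

    n_patients: int = 119
    n_controls: int = 87
    biomarkers: tuple[str, ...] = DEFAULT_COGNITIVE_PANEL
    mu_normal: float | np.ndarray = 0.0
    sd_normal: float | np.ndarray = 1.0
    mu_abnormal: float | np.ndarray = 2.0
    sd_abnormal: float | np.ndarray = 1.0
    p_stage_patient: float = 0.55
    p_stage_control: float = 0.45
    sequence: tuple[int, ...] | None = None   # pinned true ordering, else drawn
    batteries: list[BatterySpec] = field(default_factory=battery_presets)
    directions: dict[str, bool] = field(default_factory=default_directions)
    #: linear coefficients (age, sex, education) added to each harmonized
    #: biomarker; age/education are centred before the effect is applied
    covariate_effects: tuple[float, float, float] = (0.02, 0.10, -0.03)
    stages: np.ndarray | None = None          # pinned per-subject stages, else drawn
    #: also emit a regional gray-matter-volume table (AAL regions + TIV)
    #: driven by the same subject stages under a separate atrophy sequence
    include_gmv: bool = True
    gmv_atrophy_frac: float = 0.03            # fractional volume loss per abnormality unit
    gmv_noise_frac: float = 0.01              # measurement noise relative to baseline
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.biomarkers)

    def _per_marker(self, value) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float), (self.K,)).copy()

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError(f"K={self.K}: need at least 2 biomarkers")
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("n_patients and n_controls must be positive")
        sd_n = self._per_marker(self.sd_normal)
        sd_a = self._per_marker(self.sd_abnormal)
        if (sd_n <= 0).any():
            raise ValueError("sd_normal must be > 0 for every biomarker")
        if (sd_a <= 0).any():
            raise ValueError("sd_abnormal must be > 0 for every biomarker")
        mu_n = self._per_marker(self.mu_normal)
        mu_a = self._per_marker(self.mu_abnormal)
        if (mu_a <= mu_n).any():
            raise ValueError("mu_abnormal must exceed mu_normal (harmonized direction)")
        for p in (self.p_stage_patient, self.p_stage_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError("stage probabilities p_stage_* must be in [0,1]")
        if self.sequence is not None:
            if sorted(self.sequence) != list(range(self.K)):
                raise ValueError("sequence must be a permutation of 0..K-1")
        if self.stages is not None:
            st = np.asarray(self.stages)
            if st.min() < 0 or st.max() > self.K:
                raise ValueError("stages must lie in {0..K}")
        for b in self.batteries:
            b.validate()
        missing = [m for m in self.biomarkers if m not in self.directions]
        if missing:
            raise ValueError(f"directions missing for biomarkers: {missing}")


@dataclass
class GroundTruth:
    """What the generator actually used: the answer key for recovery tests."""

    sequence: np.ndarray        # position -> biomarker index; position 0 is earliest
    event_centers: np.ndarray   # K values in [0,1], increasing along sequence
    stages: np.ndarray          # per-subject integer in {0..K}
    group: np.ndarray           # per-subject "patient" / "control"
    gmv_sequence: np.ndarray | None = None      # position -> GMV feature index
    gmv_stages: np.ndarray | None = None        # per-subject stage in {0..35}


@dataclass
class Cohort:
    covariates: pd.DataFrame          # id, group, age, sex, education, clinical
    biomarkers: pd.DataFrame          # id + K raw biomarker columns
    items: dict[str, pd.DataFrame]    # battery name -> id + item columns
    directions: dict[str, bool]
    gmv: pd.DataFrame | None = None   # id + AAL region volumes (ml) + TIV


#: rough per-hemisphere gray-matter volumes (ml) used as GMV baselines
_FEATURE_BASELINE_ML = {
    "frontal": 70.0, "temporal": 45.0, "parietal": 40.0, "occipital": 30.0,
    "insula": 6.0, "cingulate": 10.0, "sensorimotor": 25.0, "broca": 8.0,
    "cerebellum": 50.0, "hippocampus": 3.2, "parahippocampus": 4.0,
    "amygdala": 1.5, "caudate": 4.0, "putamen": 4.5, "pallidum": 2.0,
    "accumbens": 0.7, "thalamus": 6.0, "vermis": 5.0,
}


def _generate_gmv(
    spec: CohortSpec, rng: np.random.Generator, n: int, stages_cog: np.ndarray,
    confound: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Regional GMV table driven by the same disease process.

    The 35 ROI features (17 per hemisphere + vermis) atrophy in a separate
    ground-truth order; a subject's GMV stage is their cognitive stage
    rescaled to the 35-feature range, so the two modalities share severity.
    Member AAL regions of a feature get the feature volume plus region
    noise, and everything scales with a subject-specific total intracranial
    volume (TIV).
    """
    from .preprocess import load_roi_scheme

    scheme = load_roi_scheme()
    features = [f + s for f in scheme["features"] for s in ("_L", "_R")]
    features.append("vermis")
    Kg = len(features)
    gmv_sequence = rng.permutation(Kg)
    # shared severity: rescale the cognitive stage to the GMV event count
    K_cog = spec.K
    gmv_stages = np.rint(stages_cog * Kg / K_cog).astype(int)
    position_of = np.empty(Kg, dtype=int)
    position_of[gmv_sequence] = np.arange(Kg)
    occurred = position_of[None, :] < gmv_stages[:, None]
    abnormality = rng.normal(np.where(occurred, 2.0, 0.0), 1.0)
    abnormality += confound[:, None]

    tiv = rng.normal(1500.0, 120.0, size=n)
    tiv_ratio = tiv / 1500.0
    data = {}
    for k, feat in enumerate(features):
        base = _FEATURE_BASELINE_ML[feat.removesuffix("_L").removesuffix("_R")]
        feat_vol = base * tiv_ratio * (1.0 - spec.gmv_atrophy_frac * abnormality[:, k])
        if feat == "vermis":
            members = scheme["midline"]["vermis"]
        else:
            stem, hemi = feat[:-2], feat[-2:]
            members = [m + hemi for m in scheme["features"][stem]]
        for m in members:
            data[m] = (feat_vol / len(members)
                       + rng.normal(0.0, spec.gmv_noise_frac * base, n))
    df = pd.DataFrame(data)
    df["TIV"] = tiv
    return df, gmv_sequence, gmv_stages


def generate_battery_items(
    battery: BatterySpec, factor_scores: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Item scores from latent factors: item = loading * factor + noise.

    ``factor_scores`` is (n_subjects, n_factors).
    """
    battery.validate()
    factor_scores = np.asarray(factor_scores, dtype=float)
    if factor_scores.ndim != 2 or factor_scores.shape[1] != battery.n_factors:
        raise ValueError(
            f"factor_scores must be (n, {battery.n_factors}), got {factor_scores.shape}"
        )
    n = factor_scores.shape[0]
    p = len(battery.items)
    noise = rng.normal(0.0, battery.noise_sd, size=(n, p)) if battery.noise_sd > 0 else 0.0
    signal = battery.loading * factor_scores[:, battery.factor_of_item]
    return pd.DataFrame(signal + noise, columns=battery.items)


def _draw_stages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n_pat, n_ctl, K = spec.n_patients, spec.n_controls, spec.K
    if spec.stages is not None:
        st = np.asarray(spec.stages, dtype=int)
        if len(st) != n_pat + n_ctl:
            raise ValueError("pinned stages must have n_patients + n_controls entries")
        return st
    pat = rng.binomial(K, spec.p_stage_patient, size=n_pat)
    ctl = rng.binomial(K, spec.p_stage_control, size=n_ctl)
    return np.concatenate([pat, ctl])


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort and return it with its ground truth.

    A subject at stage ``k`` has the biomarkers at the first ``k`` positions
    of the true sequence drawn from the abnormal distribution and the rest
    from the normal distribution (on the harmonized scale, higher = worse).
    Linear covariate confounds are then added, and the raw stored value is
    negated for markers whose natural direction is higher-is-better.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    K = spec.K
    n = spec.n_patients + spec.n_controls
    group = np.array(["patient"] * spec.n_patients + ["control"] * spec.n_controls)

    if spec.sequence is not None:
        sequence = np.asarray(spec.sequence, dtype=int)
    else:
        sequence = rng.permutation(K)
    event_centers = (np.arange(1, K + 1) - 0.5) / K
    stages = _draw_stages(spec, rng)

    # event indicator per subject x biomarker: position of marker in sequence
    position_of = np.empty(K, dtype=int)
    position_of[sequence] = np.arange(K)
    occurred = position_of[None, :] < stages[:, None]   # (n, K)

    mu_n = spec._per_marker(spec.mu_normal)
    sd_n = spec._per_marker(spec.sd_normal)
    mu_a = spec._per_marker(spec.mu_abnormal)
    sd_a = spec._per_marker(spec.sd_abnormal)
    mu = np.where(occurred, mu_a[None, :], mu_n[None, :])
    sd = np.where(occurred, sd_a[None, :], sd_n[None, :])
    harmonized = rng.normal(mu, sd) if (sd > 0).all() else mu + 0.0

    # covariates: ages/education/sex loosely matching the two study groups
    is_pat = group == "patient"
    age = np.where(is_pat, rng.normal(54.9, 9.1, n), rng.normal(49.9, 7.6, n))
    education = np.where(is_pat, rng.normal(12.0, 3.1, n), rng.normal(13.7, 3.9, n))
    sex = np.where(is_pat, rng.random(n) < 87 / 119, rng.random(n) < 50 / 87).astype(int)

    b_age, b_sex, b_edu = spec.covariate_effects
    confound = (
        b_age * (age - age.mean())
        + b_sex * (sex - sex.mean())
        + b_edu * (education - education.mean())
    )
    harmonized = harmonized + confound[:, None]

    # store raw values on each marker's natural scale
    flip = np.array(
        [-1.0 if not spec.directions[m] else 1.0 for m in spec.biomarkers]
    )
    raw = harmonized * flip[None, :]

    ids = [f"S{i:04d}" for i in range(n)]
    biomarker_df = pd.DataFrame(raw, columns=list(spec.biomarkers))
    biomarker_df.insert(0, "id", ids)

    clinical = {}
    for name, (pat_ms, ctl_ms) in _CLINICAL_PARAMS.items():
        vals = np.where(
            is_pat,
            rng.normal(*pat_ms, size=n) if pat_ms[1] > 0 else pat_ms[0],
            rng.normal(*ctl_ms, size=n) if ctl_ms[1] > 0 else ctl_ms[0],
        )
        if name in ("MAlb", "duration", "FBG", "PBG", "GLU"):
            vals = np.clip(vals, 0.0, None)
        clinical[name] = vals
    cov_df = pd.DataFrame(
        {"id": ids, "group": group, "age": age, "sex": sex, "education": education}
        | clinical
    )

    # battery items: factors driven by the matching PC biomarkers so the
    # PCA stage recovers structure that is actually disease-related; the
    # harmonized biomarker is "worse is higher", performance factors flip it
    items: dict[str, pd.DataFrame] = {}
    for battery in spec.batteries:
        factor_cols = [
            f"{battery.name}_PC{f + 1}" for f in range(battery.n_factors)
        ]
        if all(c in spec.biomarkers for c in factor_cols):
            idx = [list(spec.biomarkers).index(c) for c in factor_cols]
            factors = -harmonized[:, idx]     # performance = -abnormality
        else:
            factors = rng.standard_normal((n, battery.n_factors))
        df = generate_battery_items(battery, factors, rng)
        df.insert(0, "id", ids)
        items[battery.name] = df

    gmv_df = gmv_seq = gmv_stages = None
    if spec.include_gmv:
        gmv_df, gmv_seq, gmv_stages = _generate_gmv(spec, rng, n, stages, confound)
        gmv_df.insert(0, "id", ids)

    cohort = Cohort(
        covariates=cov_df,
        biomarkers=biomarker_df,
        items=items,
        directions=dict(spec.directions),
        gmv=gmv_df,
    )
    truth = GroundTruth(
        sequence=sequence, event_centers=event_centers, stages=stages, group=group,
        gmv_sequence=gmv_seq, gmv_stages=gmv_stages,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir: str | Path) -> None:
    """Write the cohort as CSV files plus a ground-truth table and data dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    cohort.biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    for name, df in cohort.items.items():
        df.to_csv(outdir / f"items_{name}.csv", index=False)
    with open(outdir / "biomarker_manifest.json", "w") as fh:
        json.dump({"higher_is_worse": cohort.directions}, fh, indent=2)

    K = len(truth.sequence)
    pd.DataFrame(
        {
            "position": np.arange(K),
            "biomarker_index": truth.sequence,
            "biomarker": [cohort.biomarkers.columns[1:][i] for i in truth.sequence],
            "event_center": truth.event_centers,
        }
    ).to_csv(outdir / "truth_sequence.csv", index=False)
    pd.DataFrame(
        {"id": cohort.biomarkers["id"], "group": truth.group, "stage": truth.stages}
    ).to_csv(outdir / "truth_stages.csv", index=False)
    if cohort.gmv is not None:
        cohort.gmv.to_csv(outdir / "gmv.csv", index=False)
        Kg = len(truth.gmv_sequence)
        pd.DataFrame(
            {
                "position": np.arange(Kg),
                "feature_index": truth.gmv_sequence,
                "event_center": (np.arange(1, Kg + 1) - 0.5) / Kg,
            }
        ).to_csv(outdir / "truth_gmv_sequence.csv", index=False)

    dictionary = {
        "covariates.csv": "id, group (patient/control), age (years), sex (1=male), "
        "education (years), FBG/PBG/GLU (mmol/L), HbA1c (%), MAlb (mg/L), "
        "duration (years)",
        "biomarkers.csv": "id plus one column per biomarker on its natural scale "
        "(see biomarker_manifest.json for direction flags)",
        "items_<battery>.csv": "id plus one column per battery item score",
        "gmv.csv": "id plus AAL region gray-matter volumes (ml) and TIV",
        "truth_sequence.csv": "ground-truth event ordering and event centers",
        "truth_stages.csv": "ground-truth per-subject stage in {0..K}",
        "truth_gmv_sequence.csv": "ground-truth atrophy ordering of the 35 ROI features",
    }
    with open(outdir / "data_dictionary.json", "w") as fh:
        json.dump(dictionary, fh, indent=2)
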