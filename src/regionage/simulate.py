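"""Synthetic cohort + regional-volume generator.

Emulates the statistical structure of a large population-imaging cohort of
middle- and older-aged women (UK Biobank-like): chronological age from a
truncated normal, parity (number of live childbirths) from an empirical
multinomial, nuisance variables (scan site, intracranial volume, surface
quality scores, ethnicity) with configurable loadings on every region, and
regional gray-matter volumes that decline linearly with age and carry a
block-structured residual covariance so that covariance-based feature
clustering has a known ground truth.

An optional localized exposure effect adds volume proportional to the
number of childbirths in a configurable set of regions (by default the
striatal/limbic sub-block, strongest in the accumbens), emulating "less
apparent brain aging" with parity: because volumes shrink with age, a
positive volume offset per birth translates into a *negative* association
between the brain-age delta and parity downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import atlas

# ---------------------------------------------------------------------------
# Reference demographics of the cohort being emulated (UK Biobank women with
# usable T1 imaging). Used to calibrate marginal distributions and for the
# sample-bookkeeping arithmetic.
# ---------------------------------------------------------------------------

#: Women per number of live childbirths (0..9) in the full analysis sample.
REFERENCE_PARITY_COUNTS: tuple[int, ...] = (4297, 2459, 8770, 3334, 729, 142, 43, 7, 5, 1)

#: Participants with usable imaging before the exposure-missingness exclusion,
#: and the number missing the childbirth count.
REFERENCE_USABLE_N: int = 19_796
REFERENCE_MISSING_EXPOSURE_N: int = 9

#: Per-parity counts (0..9) of the held-out replication subsample.
REPLICATION_PARITY_COUNTS: tuple[int, ...] = (2065, 1014, 3912, 1493, 311, 67, 13, 3, 1, 1)

REFERENCE_AGE_MEAN: float = 63.59
REFERENCE_AGE_SD: float = 7.38
REFERENCE_AGE_RANGE: tuple[float, float] = (45.13, 82.27)

_SITE_PROBS = {"site_a": 5139 / 19787, "site_b": 11906 / 19787, "site_c": 2742 / 19787}
_ETHNICITY_PROBS = {
    "white": 0.9706, "black": 0.0069, "mixed": 0.0054, "asian": 0.0075,
    "chinese": 0.0037, "other": 0.0055, "unknown": 0.0003,
}
_EDUCATION_PROBS = {
    "degree": 0.4471, "a_levels": 0.1409, "o_levels": 0.2491,
    "nvq": 0.0317, "professional": 0.0565, "none": 0.0591,
}
_MENOPAUSE_PROBS = {
    "yes": 6117 / 19781, "no": 10737 / 19781,
    "unsure_hysterectomy": 1912 / 19781, "unsure_other": 1015 / 19781,
}

#: Default localized exposure effect, expressed in years-of-aging offset per
#: childbirth (volume preserved by ``effect_years`` years of age-related
#: decline per birth).  The effect is confined to the striatal/limbic
#: sub-block and strongest in the accumbens; the non-focal regions sit at
#: 0.9x the focal effect, the (pilot-measured) redundancy point at which
#: they are marginally associated with the exposure but carry essentially
#: no information beyond the accumbens — emulating a focal effect whose
#: neighbours co-vary with it.  The absolute scale is set for design power
#: at n = 5,000 (see docs/methods.md).
DEFAULT_EXPOSURE_EFFECT_YEARS: dict[str, float] = {
    "parahippocampal": 1.98,
    "thalamus": 1.98,
    "putamen": 1.98,
    "hippocampus": 1.98,
    "amygdala": 1.98,
    "accumbens": 2.20,
}


@dataclass
class RegionSpec:
    """Generating model for one (hemisphere-averaged) region."""

    baseline_mean: float          # mm^3 at the cohort mean age
    age_slope: float              # mm^3 per year of age
    noise_sd: float               # mm^3 residual SD
    block_id: int                 # covariance block (top-level cluster)
    subblock_id: str              # nested covariance sub-block
    exposure_slope: float = 0.0   # mm^3 per childbirth
    icv_coef: float = 0.0         # mm^3 per mm^3 of intracranial volume
    qc_coef: float = 0.0          # mm^3 per unit of the quality score
    site_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)  # mm^3 per site
    bilateral: bool = True


@dataclass
class SimulationConfig:
    n_participants: int
    seed: int
    age_mean: float = REFERENCE_AGE_MEAN
    age_sd: float = REFERENCE_AGE_SD
    age_range: tuple[float, float] = REFERENCE_AGE_RANGE
    parity_probs: tuple[float, ...] = tuple(
        c / sum(REFERENCE_PARITY_COUNTS) for c in REFERENCE_PARITY_COUNTS
    )
    region_spec: dict[str, RegionSpec] = field(default_factory=dict)
    block_correlation: float = 0.5      # residual corr between sub-blocks of one block
    subblock_correlation: float = 0.8   # residual corr within a sub-block
    missing_parity_rate: float = REFERENCE_MISSING_EXPOSURE_N / REFERENCE_USABLE_N
    missing_parity_exact: int | None = None  # overrides the rate when set
    diagnosis_rate: float = 0.0
    icv_mean: float = 1.45e6
    icv_sd: float = 1.3e5
    qc_mean: float = -110.0
    qc_sd: float = 35.0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        p = np.asarray(self.parity_probs, dtype=float)
        if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("parity_probs must be a probability vector summing to 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range bounds must be ordered")
        if not (0.0 <= self.block_correlation <= self.subblock_correlation < 1.0):
            raise ValueError(
                "need 0 <= block_correlation <= subblock_correlation < 1"
            )
        for name, spec in self.region_spec.items():
            if spec.noise_sd <= 0:
                raise ValueError(f"noise_sd must be positive (region {name!r})")
        for rate in (self.missing_parity_rate, self.diagnosis_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def default_region_spec(
    exposure_effect_years: dict[str, float] | None = None,
    confounders: bool = True,
) -> dict[str, RegionSpec]:
    """Region specs for the full 43-region atlas.

    Age slopes are ~-0.25%/yr (cortical) and -0.3%/yr (subcortical) of the
    baseline volume; residual SD is 1.5x the age-signal SD so each region
    alone predicts age with r ~ 0.55.  ``exposure_effect_years`` maps region
    name -> years-of-aging-equivalent volume offset per childbirth.
    """
    effect = exposure_effect_years or {}
    spec: dict[str, RegionSpec] = {}
    for name in atlas.AVERAGED_REGIONS:
        base = atlas.BASELINE_VOLUME[name]
        slope_frac = 0.003 if atlas.compartment_of(name) == "subcortical" else 0.0025
        age_slope = -slope_frac * base
        noise_sd = 1.5 * abs(age_slope) * REFERENCE_AGE_SD
        block = atlas.CLUSTER_OF_REGION[name]
        if name in atlas.SUBCLUSTER3_CORTICAL:
            sub = "3a"
        elif name in atlas.SUBCLUSTER3_SUBCORTICAL:
            sub = "3b"
        else:
            sub = str(block)
        spec[name] = RegionSpec(
            baseline_mean=base,
            age_slope=age_slope,
            noise_sd=noise_sd,
            block_id=block,
            subblock_id=sub,
            exposure_slope=-age_slope * effect.get(name, 0.0),
            icv_coef=0.3 * base / 1.45e6 if confounders else 0.0,
            qc_coef=0.0005 * base if confounders else 0.0,
            site_offsets=(0.005 * base, 0.0, -0.005 * base) if confounders else (0.0, 0.0, 0.0),
            bilateral=name not in atlas.MIDLINE_REGIONS,
        )
    return spec


def default_config(
    n_participants: int,
    seed: int,
    exposure_effect: str | dict[str, float] | None = "focal",
    confounders: bool = True,
    **overrides,
) -> SimulationConfig:
    """Study-condition configuration.

    ``exposure_effect``: ``"focal"`` for the default localized striatal/limbic
    effect, ``None`` for a null cohort, or an explicit region -> effect-years
    mapping.
    """
    if exposure_effect == "focal":
        effect = DEFAULT_EXPOSURE_EFFECT_YEARS
    elif exposure_effect is None:
        effect = {}
    else:
        effect = dict(exposure_effect)
    cfg = SimulationConfig(
        n_participants=n_participants,
        seed=seed,
        region_spec=default_region_spec(effect, confounders=confounders),
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _raw_column_specs(config: SimulationConfig):
    """Expand region specs into raw per-hemisphere columns.

    Left/right columns get a fixed +/-1% baseline asymmetry and share the
    region's covariance sub-block.
    """
    cols, specs, scale = [], [], []
    for name, spec in config.region_spec.items():
        if spec.bilateral:
            cols.extend([f"lh_{name}", f"rh_{name}"])
            specs.extend([spec, spec])
            scale.extend([1.01, 0.99])
        else:
            cols.append(name)
            specs.append(spec)
            scale.append(1.0)
    return cols, specs, scale


def _noise_correlation(specs: list[RegionSpec], config: SimulationConfig) -> np.ndarray:
    m = len(specs)
    corr = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                corr[i, j] = 1.0
            elif specs[i].subblock_id == specs[j].subblock_id:
                corr[i, j] = config.subblock_correlation
            elif specs[i].block_id == specs[j].block_id:
                corr[i, j] = config.block_correlation
    return corr


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: returns ``(cohort, features)``.

    ``cohort`` is one row per participant (demographics, exposure,
    covariates, QC); ``features`` is the participant x raw-region volume
    matrix (mm^3), both indexed by ``participant_id``.  Identical config
    (including seed) gives bit-identical output.
    """
    config.validate()
    if not config.region_spec:
        raise ValueError("config.region_spec is empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)

    parity = rng.choice(len(config.parity_probs), size=n, p=np.asarray(config.parity_probs))

    site = rng.choice(list(_SITE_PROBS), size=n, p=list(_SITE_PROBS.values()))
    eth_p = np.array(list(_ETHNICITY_PROBS.values()))
    ethnicity = rng.choice(list(_ETHNICITY_PROBS), size=n, p=eth_p / eth_p.sum())
    edu_p = np.array(list(_EDUCATION_PROBS.values()))
    education = rng.choice(list(_EDUCATION_PROBS), size=n, p=edu_p / edu_p.sum())
    menopause = rng.choice(list(_MENOPAUSE_PROBS), size=n, p=list(_MENOPAUSE_PROBS.values()))

    icv = rng.normal(config.icv_mean, config.icv_sd, size=n)
    qc_shared = rng.normal(size=n)
    qc_lh = config.qc_mean + config.qc_sd * (np.sqrt(0.7) * qc_shared + np.sqrt(0.3) * rng.normal(size=n))
    qc_rh = config.qc_mean + config.qc_sd * (np.sqrt(0.7) * qc_shared + np.sqrt(0.3) * rng.normal(size=n))

    bmi = np.clip(rng.normal(27.0, 4.7, size=n), 15.0, 55.0)
    diabetic = rng.random(n) < 0.05
    hypertension = rng.random(n) < 0.30
    smoking = rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1])
    alcohol = rng.choice(np.arange(6), size=n, p=[0.05, 0.10, 0.25, 0.30, 0.20, 0.10])
    oc_use = rng.random(n) < 0.80
    hrt_use = rng.random(n) < 0.37
    diagnosis_excluded = rng.random(n) < config.diagnosis_rate

    age_first = np.full(n, np.nan)
    parous = parity >= 1
    age_first[parous] = np.clip(rng.normal(27.08, 5.01, size=int(parous.sum())), 14.0, 47.0)

    # regional volumes
    cols, specs, scale = _raw_column_specs(config)
    corr = _noise_correlation(specs, config)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(cols)))
    noise = z @ chol.T

    site_idx = pd.Categorical(site, categories=list(_SITE_PROBS)).codes
    qc_person = (qc_lh + qc_rh) / 2.0
    values = np.empty((n, len(cols)))
    for j, (spec, sc) in enumerate(zip(specs, scale)):
        values[:, j] = (
            spec.baseline_mean * sc
            + spec.age_slope * (age - config.age_mean)
            + spec.exposure_slope * parity
            + spec.icv_coef * (icv - config.icv_mean)
            + spec.qc_coef * (qc_person - config.qc_mean)
            + np.asarray(spec.site_offsets)[site_idx]
            + spec.noise_sd * noise[:, j]
        )

    # missingness on the exposure (MCAR)
    n_childbirths = parity.astype(float)
    if config.missing_parity_exact is not None:
        miss_idx = rng.choice(n, size=config.missing_parity_exact, replace=False)
        n_childbirths[miss_idx] = np.nan
    elif config.missing_parity_rate > 0:
        n_childbirths[rng.random(n) < config.missing_parity_rate] = np.nan

    ids = pd.Index([f"P{i:07d}" for i in range(n)], name="participant_id")
    cohort = pd.DataFrame(
        {
            "age": age,
            "n_childbirths": n_childbirths,
            "age_first_birth": age_first,
            "parous": parous,
            "site": site,
            "education": education,
            "bmi": bmi,
            "diabetic": diabetic,
            "hypertension": hypertension,
            "smoking": smoking,
            "alcohol": alcohol,
            "menopausal_status": menopause,
            "oc_use": oc_use,
            "hrt_use": hrt_use,
            "diagnosis_excluded": diagnosis_excluded,
            "qc_score_lh": qc_lh,
            "qc_score_rh": qc_rh,
            "icv": icv,
            "ethnicity": ethnicity,
        },
        index=ids,
    )
    features = pd.DataFrame(values, index=ids, columns=cols)
    if (features.to_numpy() < 0).any():
        raise RuntimeError("simulated a negative volume; check region specs")
    return cohort, features


def table1_moments(counts) -> tuple[float, float]:
    """Count-weighted mean and sample SD of parity from per-parity counts.

    ``counts[k]`` is the number of women with ``k`` childbirths.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("counts must be non-empty with positive total")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    k = np.arange(c.size, dtype=float)
    n = c.sum()
    mean = float((k * c).sum() / n)
    if n > 1:
        var = float(((k - mean) ** 2 * c).sum() / (n - 1))
    else:
        var = 0.0
    return mean, float(np.sqrt(var))


def write_tables(cohort: pd.DataFrame, features: pd.DataFrame,
                 config: SimulationConfig, outdir: str | Path) -> None:
    """Emit cohort/features as CSV and the config (with seed) as JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv")
    features.to_csv(out / "features.csv")
    cfg = asdict(config)
    with open(out / "simulation_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
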