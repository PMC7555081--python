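"""Sample exclusions, hemisphere averaging, and nuisance residualization.

The exclusion stage mirrors standard population-imaging QC: participants
with a recorded diagnosis flag, with |z| > 4 on the surface-quality score
or on the global gray-matter summaries (mean cortical / mean subcortical
volume), or with a missing exposure value are dropped, and the per-flag
counts are reported.  z-scores are computed after the diagnosis exclusion
but before the metric exclusions; the retained set is the complement of
the union of all flags, so the result does not depend on evaluation order.

Residualization replaces every feature column by the residual of an OLS
fit on nuisance covariates (site, quality score, intracranial volume,
ethnicity by default).  It is fitted on the full analysis sample, as a
preprocessing step preceding any train/test split (see README for the
leakage caveat this implies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas

DEFAULT_NUISANCE = ("site", "qc_score", "icv", "ethnicity")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    counts: dict[str, int]              # per-flag counts
    n_union: int                        # |union of all flags|
    flags: pd.DataFrame = field(repr=False)  # per-participant boolean flags

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "flags"}
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _zscore(x: pd.Series, label: str) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"zero-variance QC metric {label!r}: z-score undefined")
    return (x - x.mean()) / sd


def exclude_participants(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    sd_threshold: float = 4.0,
    exposure_col: str = "n_childbirths",
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Apply the exclusion rules; returns retained tables plus a QCReport.

    Flags: ``diagnosis`` (pre-recorded flag), ``qc_outlier`` (|z| of the
    hemisphere-averaged quality score strictly above ``sd_threshold``),
    ``cortical_gm_outlier`` / ``subcortical_gm_outlier`` (|z| of mean
    cortical / subcortical volume), ``missing_exposure``.  A value at
    exactly ``sd_threshold`` SD is retained.
    """
    if not cohort.index.equals(features.index):
        raise ValueError("cohort and features must share the same participant index")
    meta = atlas.region_metadata(list(features.columns))
    cortical_cols = meta.index[meta["compartment"] == "cortical"]
    subcort_cols = meta.index[meta["compartment"] == "subcortical"]

    diagnosis = cohort["diagnosis_excluded"].astype(bool)
    base = ~diagnosis  # z-scores on the post-diagnosis sample

    qc = (cohort["qc_score_lh"] + cohort["qc_score_rh"]) / 2.0
    flags = pd.DataFrame(index=cohort.index)
    flags["diagnosis"] = diagnosis
    for label, series in (
        ("qc_outlier", qc),
        ("cortical_gm_outlier", features[cortical_cols].mean(axis=1) if len(cortical_cols) else None),
        ("subcortical_gm_outlier", features[subcort_cols].mean(axis=1) if len(subcort_cols) else None),
    ):
        if series is None:
            flags[label] = False
            continue
        z = _zscore(series[base], label)
        f = pd.Series(False, index=cohort.index)
        f.loc[z.index] = z.abs() > sd_threshold
        flags[label] = f
    flags["missing_exposure"] = cohort[exposure_col].isna()

    union = flags.any(axis=1)
    keep = ~union
    report = QCReport(
        n_input=len(cohort),
        n_retained=int(keep.sum()),
        counts={c: int(flags[c].sum()) for c in flags.columns},
        n_union=int(union.sum()),
        flags=flags,
    )
    return cohort.loc[keep].copy(), features.loc[keep].copy(), report


def average_hemispheres(features: pd.DataFrame) -> pd.DataFrame:
    """Average paired lh_/rh_ columns; midline columns pass through.

    Output column names are de-lateralized region names.
    """
    meta = atlas.region_metadata(list(features.columns))
    out: dict[str, pd.Series] = {}
    for region, grp in meta.groupby("region", sort=False):
        hemis = set(grp["hemisphere"])
        if hemis == {"left", "right"}:
            out[region] = features[list(grp.index)].mean(axis=1)
        elif hemis <= {"midline", "both"}:
            out[region] = features[grp.index[0]]
        else:
            raise ValueError(f"unpaired lateral region: {region!r} (have {sorted(hemis)})")
    return pd.DataFrame(out, index=features.index)


def _build_design(nuisance: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + one-hot (first level dropped) categoricals."""
    parts = [pd.Series(1.0, index=nuisance.index, name="intercept")]
    for col in nuisance.columns:
        s = nuisance[col]
        if s.dtype == bool:
            parts.append(s.astype(float))
        elif pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns via successive rank checks
        bad = []
        kept: list[str] = []
        for c in X.columns:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    return X


def residualize(features: pd.DataFrame, nuisance: pd.DataFrame) -> pd.DataFrame:
    """Replace each feature by its OLS residual on intercept + nuisance.

    Residual columns are orthogonal to every nuisance regressor; applying
    the operation twice is a no-op (idempotent).
    """
    if not features.index.equals(nuisance.index):
        raise ValueError("features and nuisance must share the same index")
    X = _build_design(nuisance).to_numpy()
    # standardize non-intercept columns for conditioning (ICV is ~1e6)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / scale
    Xs[:, 0] = 1.0
    Y = features.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xs, Y, rcond=None)
    resid = Y - Xs @ beta
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def default_nuisance(cohort: pd.DataFrame) -> pd.DataFrame:
    """Standard nuisance table: site, averaged QC score, ICV, ethnicity."""
    return pd.DataFrame(
        {
            "site": cohort["site"],
            "qc_score": (cohort["qc_score_lh"] + cohort["qc_score_rh"]) / 2.0,
            "icv": cohort["icv"],
            "ethnicity": cohort["ethnicity"],
        },
        index=cohort.index,
    )
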