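#!/usr/bin/env python
"""QC exclusions and nuisance residualization.

Reads the simulated tables from results/data/, applies the exclusion
rules (diagnosis flag, |z| > 4 on QC score and global gray-matter means,
missing exposure), residualizes the volumes on site, QC score,
intracranial volume and ethnicity, averages hemispheres, and writes the
processed 43-column feature table plus the QC report.
"""

from pathlib import Path

import pandas as pd

from regionage.preprocess import (
    average_hemispheres,
    default_nuisance,
    exclude_participants,
    residualize,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    cohort = pd.read_csv(BASE / "data" / "cohort.csv", index_col="participant_id")
    features = pd.read_csv(BASE / "data" / "features.csv", index_col="participant_id")

    cohort, features, report = exclude_participants(cohort, features)
    print("exclusion counts:", report.counts)
    print(f"retained {report.n_retained} of {report.n_input}")
    report.to_json(BASE / "qc_report.json")

    resid = residualize(features, default_nuisance(cohort))
    averaged = average_hemispheres(resid)
    averaged.to_csv(BASE / "data" / "features_processed.csv")
    cohort.to_csv(BASE / "data" / "cohort_retained.csv")
    print(f"residualized + hemisphere-averaged features: {averaged.shape[1]} columns")


if __name__ == "__main__":
    main()
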