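#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws the default study conditions — a UK Biobank-like cohort of
middle-aged women with 85 regional brain volumes, nuisance structure, and
a localized parity effect in the striatal/limbic regions — and writes the
cohort and feature tables under results/data/.
"""

from pathlib import Path

from regionage import default_config, simulate_cohort, table1_moments
from regionage.simulate import REFERENCE_PARITY_COUNTS, write_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
N, SEED = 5000, 42


def main():
    cfg = default_config(N, seed=SEED)
    cohort, features = simulate_cohort(cfg)
    write_tables(cohort, features, cfg, OUT)

    ref_mean, ref_sd = table1_moments(REFERENCE_PARITY_COUNTS)
    obs = cohort["n_childbirths"].dropna()
    print(f"cohort: n={len(cohort)}, features: {features.shape[1]} regional volumes")
    print(f"age: mean {cohort['age'].mean():.2f}, sd {cohort['age'].std():.2f}, "
          f"range {cohort['age'].min():.2f}-{cohort['age'].max():.2f}")
    print(f"parity: mean {obs.mean():.2f} (reference {ref_mean:.2f}), "
          f"sd {obs.std():.2f} (reference {ref_sd:.2f}), "
          f"missing {cohort['n_childbirths'].isna().sum()}")
    print(f"parous: {int(cohort['parous'].sum())} / nulliparous: {int((~cohort['parous']).sum())}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
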