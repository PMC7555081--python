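#!/usr/bin/env python
"""Replication design: train a global model, test on held-out women.

Fits the global 43-region brain-age model on one half of the cohort and
evaluates the parity association on the disjoint other half, including
the weighted linear/quadratic group fits to the parity-group means of the
age-corrected deltas.
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from regionage import FAST_PARAMS, RunConfig, default_config, simulate_cohort
from regionage.pipeline import replicate_split

N, SEED = 6000, 77


def main():
    cfg = RunConfig(seed=SEED, sim=default_config(N, seed=SEED),
                    params=replace(FAST_PARAMS, seed=SEED))
    cohort, _ = simulate_cohort(cfg.sim)
    ids = cohort.index
    train, test = ids[: N // 2], ids[N // 2:]
    rep = replicate_split(cfg, train, test)

    m = rep.metrics
    print(f"global model on train (n={rep.n_train}) -> test (n={rep.n_test}):")
    print(f"  r={m.r:.2f} [{m.r_ci[0]:.2f}, {m.r_ci[1]:.2f}], R2={m.r2:.2f}, "
          f"RMSE={m.rmse:.2f} y, MAE={m.mae:.2f} y")
    a = rep.association
    print(f"test-set association: beta={a.beta:+.3f}, se={a.se:.3f}, "
          f"t={a.t:+.2f}, p={a.p:.2e} (n={a.n})")
    p = rep.poly
    print("polynomial group fits (weighted by 1/SE^2 of group means):")
    print(f"  linear only : beta={p.beta_linear_only:+.3f} +/- {p.beta_linear_only_se:.3f} "
          f"(F={p.f_linear:.2f}, p={p.p_linear:.2e})")
    print(f"  quadratic   : beta={p.beta:+.3f} +/- {p.beta_se:.3f}, "
          f"gamma={p.gamma:+.4f} +/- {p.gamma_se:.4f} (F={p.f_quadratic:.2f})")
    print(f"  linear vs quadratic: F={p.f_compare:.3f}, p={p.p_compare:.3f}")
    print("test-set parity group counts:")
    print(rep.group_counts.to_string())


if __name__ == "__main__":
    main()
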