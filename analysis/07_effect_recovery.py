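#!/usr/bin/env python
"""End-to-end recovery of the planted localized exposure effect.

Runs the full pipeline on 20 seeded synthetic cohorts (n = 5,000) with
the default striatal/limbic effect (strongest in the accumbens) and
scores, per replicate: (i) the accumbens-bearing cluster has the most
negative association with parity, (ii) its association differs
significantly from every unaffected cluster by the correlated-estimates
Z test, (iii) the leave-one-region-out likelihood test flags the
accumbens and only the accumbens (BH q < 0.05).
"""

from regionage.experiments import recovery_study

SEED = 0


def main():
    study = recovery_study(n_replicates=20, n=5000, seed=SEED)
    print("recovery rates over 20 replicates (n = 5,000):")
    print(f"  focal cluster ranked most negative : {100*study.rate('rank'):.0f}%")
    print(f"  Z significant vs all other clusters: {100*study.rate('z'):.0f}%")
    print(f"  accumbens uniquely flagged (nested): {100*study.rate('nested'):.0f}%")
    print(f"  all three jointly                  : {100*study.rate('all'):.0f}%")


if __name__ == "__main__":
    main()
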