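#!/usr/bin/env python
"""Paired blood / bone-marrow (PBS/BMS) concordance of sncRNA expression.

Simulates a paired cohort (12 subjects, two deep libraries each) at the
default shared-signal fraction and reports per-category pooled r (on
per-feature centered log10(RPM+1) deviations), the raw pooled r, and the
mean per-subject r.  A sweep over the shared-signal fraction shows the
estimator tracking the generator truth monotonically.
"""

import argparse
from pathlib import Path

from serumrna.concordance import all_category_concordance, category_concordance
from serumrna.io import write_tsv
from serumrna.reference import build_default_reference
from serumrna.simulate import CohortConfig, default_mixture_config, \
    simulate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

ref = build_default_reference(args.seed)
mcfg = default_mixture_config(seed=args.seed)


def paired(w):
    cohort = simulate_cohort(
        CohortConfig(n_control=2, n_aml=10, paired_bms=True,
                     bms_shared_signal_fraction=w, nb_dispersion=0.02,
                     library_size_range=(200_000, 300_000),
                     seed=args.seed + 300), mcfg, ref)
    return cohort.counts.drop(index="cel-miR-39"), cohort


counts, cohort = paired(0.8)
table = all_category_concordance(counts, cohort.samples, cohort.features)
write_tsv(table, args.outdir / "concordance.tsv", args.seed)
print("per-category PBS/BMS concordance at shared-signal fraction 0.8:")
print(table.round(3).to_string())

print("\npooled r across the shared-signal sweep:")
for w in (0.0, 0.4, 0.8, 1.0):
    c, coh = paired(w)
    r = category_concordance(c, coh.samples, coh.features, None).r
    print(f"  fraction {w:.1f} -> r = {r:+.3f}")
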