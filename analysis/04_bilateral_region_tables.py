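#!/usr/bin/env python
"""Detect injured regions by rank-ordered ipsilateral-vs-contralateral statistics.

Simulates an injured cohort (n = 5) carrying the FA shifts measured in the
published central-amygdala, laterodorsal-thalamus and CA1 rows, runs the
full detection pipeline, and writes the rank-ordered bilateral table —
the phantom analogue of the published significance tables.
"""

from pathlib import Path

from ratlas_ia.pipeline import analyze_cohort
from ratlas_ia.stats import adjust_pvalues
from ratlas_ia.synthetic import InjuryEffect, simulate_cohort, small_spec

ROOT = Path(__file__).resolve().parent.parent / "results"

EFFECTS = (
    InjuryEffect("central amygdala", "right", "fa", 0.168),
    InjuryEffect("laterodorsal thalamus", "right", "fa", -0.160),
    InjuryEffect("CA1 dorsal hippocampus", "right", "fa", 0.074),
)


def main() -> None:
    spec = small_spec(injury_effects=EFFECTS, mirror_s0=True)
    cohort = simulate_cohort(spec, n_subjects=5, inter_subject_sd=0.05,
                             seed=1, displacement=False)
    table = analyze_cohort(cohort, index="FA", site="rostral")
    table = adjust_pvalues(table, "benjamini_hochberg")
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "table_FA_injured_cohort.tsv")
    print("rank-ordered bilateral FA table (injured phantom cohort, n = 5):")
    cols = ["region_name", "contra_mean", "ipsi_mean", "arrow", "t", "p", "q"]
    print(table.table[cols].to_string(index=False))
    n_sig = len(table.significant)
    print(f"\n{n_sig} of {len(table.table)} regions significant at p < {table.cutoff}; "
          f"all three seeded effects should rank on top with the planted direction")


if __name__ == "__main__":
    main()
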