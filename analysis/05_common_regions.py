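#!/usr/bin/env python
"""Intersect the published significant-region sets across the two injury sites.

For each anisotropy index (FA, RD, AD) the transcribed published tables for
the rostral and caudal insults are intersected; regions significant after
both injuries are reported with a direction-consistency flag.  The lone
direction-inconsistent region (lateral amygdala, FA) is called out.
"""

from pathlib import Path

import pandas as pd

from ratlas_ia.reference_tables import INDICES, published_table
from ratlas_ia.stats import common_regions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for index in INDICES:
        inter = common_regions(published_table(index, "rostral"), published_table(index, "caudal"))
        inter.to_csv(out / f"common_regions_{index}.tsv", sep="\t", index=False)
        print(f"{index}: {len(inter)} regions significant after both injuries")
        print(inter.to_string(index=False))
        bad = inter[~inter.direction_consistent]
        if len(bad):
            print(f"  direction-inconsistent exception(s): {', '.join(bad.region_name)}")
        print()


if __name__ == "__main__":
    main()
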