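"""Bilateral region statistics: ipsilateral vs contralateral comparison tables.

The experimental design uses the non-concussed hemisphere as a within-animal
control.  For each atlas region the cohort pipeline runs a two-tailed paired
t-test across animals on (ipsilateral mean - contralateral mean); printed
summary tables (mean, SD per side) can only be recomputed with a two-sample
test, so a summary-statistic t (pooled or Welch) is provided alongside.

Output rows are rank-ordered by ascending p (ties broken by |t| descending,
then region name) and carry a direction arrow: "up" iff the ipsilateral mean
exceeds the contralateral mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonTable",
    "t_from_summary",
    "cohort_region_table",
    "common_regions",
    "adjust_pvalues",
]

ARROW_UP = "↑"
ARROW_DOWN = "↓"

TABLE_COLUMN_ORDER = [
    "region_name",
    "contra_mean",
    "contra_sd",
    "ipsi_mean",
    "arrow",
    "ipsi_sd",
    "t",
    "p",
    "n",
    "index",
]


@dataclass
class ComparisonTable:
    """Rank-ordered bilateral comparison for one anisotropy index.

    ``table`` holds one row per region sorted ascending by p; ``significant``
    filters at the cutoff (the "reported" view mirroring published tables).
    """

    table: pd.DataFrame
    index: str
    site: str = "custom"
    cutoff: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table.p < self.cutoff].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        cols = [c for c in TABLE_COLUMN_ORDER if c in self.table.columns]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: returns (t, df, two-tailed p).

    ``mean2`` is conventionally the ipsilateral side, so t > 0 means an
    ipsilateral increase.  ``variant`` is "pooled" (equal-variance, df =
    n1+n2-2) or "welch" (Satterthwaite df).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float("inf"), float(n1 + n2 - 2), 0.0
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (mean2 - mean1) / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohort_region_table(
    region_means: pd.DataFrame,
    index: str,
    ipsilateral_side: str = "right",
    site: str = "custom",
    cutoff: float = 0.05,
) -> ComparisonTable:
    """Paired bilateral comparison across a cohort of animals.

    ``region_means`` is long-format with columns subject, region_name, left,
    right (per-subject per-region hemisphere means).  Pairing is within
    animal: the test statistic is a two-tailed paired t across subjects on
    ipsilateral - contralateral.  Zero within-pair variance yields a
    machine-floor p with a warning (noiseless phantoms are legal inputs).
    """
    req = {"subject", "region_name", "left", "right"}
    if not req <= set(region_means.columns):
        raise ValueError(f"region_means needs columns {req}")
    if ipsilateral_side not in ("left", "right"):
        raise ValueError("ipsilateral_side must be 'left' or 'right'")
    contra_side = "left" if ipsilateral_side == "right" else "right"

    rows = []
    for region, grp in region_means.groupby("region_name", sort=False):
        ipsi = grp[ipsilateral_side].to_numpy(float)
        contra = grp[contra_side].to_numpy(float)
        n = len(grp)
        if n < 2:
            raise ValueError(f"region {region!r}: need >= 2 subjects, got {n}")
        if np.isnan(ipsi).any() or np.isnan(contra).any():
            raise ValueError(f"region {region!r}: missing side means")
        diff = ipsi - contra
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                warnings.warn(
                    f"region {region!r}: zero within-pair variance, p floored",
                    stacklevel=2,
                )
                t = np.sign(diff.mean()) * np.inf
                p = float(np.finfo(float).tiny)
        else:
            t, p = sps.ttest_rel(ipsi, contra)
        im, cm = float(ipsi.mean()), float(contra.mean())
        rows.append(
            {
                "region_name": region,
                "contra_mean": cm,
                "contra_sd": float(contra.std(ddof=1)),
                "ipsi_mean": im,
                "ipsi_sd": float(ipsi.std(ddof=1)),
                "arrow": "" if im == cm else (ARROW_UP if im > cm else ARROW_DOWN),
                "t": float(t),
                "p": float(max(p, np.finfo(float).tiny)),
                "n": n,
                "index": index,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["p", "t", "region_name"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "t" else s,
    ).reset_index(drop=True)
    return ComparisonTable(table=df, index=index, site=site, cutoff=cutoff)


def common_regions(a: ComparisonTable, b: ComparisonTable) -> pd.DataFrame:
    """Regions significant in both tables, with direction-consistency flags.

    Returns a DataFrame (region_name, arrow_a, arrow_b, direction_consistent)
    over the intersection of the two significant sets; regions whose arrows
    disagree are the explicit exceptions.
    """
    if a.index != b.index:
        raise ValueError(f"tables compare different indices: {a.index} vs {b.index}")
    sig_a = a.significant.set_index("region_name")
    sig_b = b.significant.set_index("region_name")
    common = sorted(set(sig_a.index) & set(sig_b.index))
    rows = [
        {
            "region_name": r,
            "arrow_a": sig_a.loc[r, "arrow"],
            "arrow_b": sig_b.loc[r, "arrow"],
            "direction_consistent": sig_a.loc[r, "arrow"] == sig_b.loc[r, "arrow"],
        }
        for r in common
    ]
    return pd.DataFrame(rows, columns=["region_name", "arrow_a", "arrow_b", "direction_consistent"])


def adjust_pvalues(table: ComparisonTable, method: str = "none") -> ComparisonTable:
    """Append Benjamini-Hochberg q-values; raw p-values are never overwritten.

    ``method`` "none" reproduces uncorrected reporting (q = p copied for
    interface uniformity is *not* done; no q column is added).
    """
    if method == "none":
        return table
    if method != "benjamini_hochberg":
        raise ValueError("method must be 'none' or 'benjamini_hochberg'")
    df = table.table.copy()
    p = df.p.to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    df["q"] = sps.false_discovery_control(p, method="bh")
    return ComparisonTable(table=df, index=table.index, site=table.site, cutoff=table.cutoff)
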