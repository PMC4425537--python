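"""Published bilateral region summary statistics for worked-example checks.

These are the printed ipsilateral-vs-contralateral summary tables (mean, SD
per hemisphere, direction arrow, reported p) from the rat fluid-percussion
concussion experiment this pipeline models: FA, RD and AD comparisons for
right rostral (n = 5) and right caudal (n = 8) cortical insults, listing only
regions reported significant at p < 0.05 and rank-ordered by p.

Diffusivity (RD/AD) values are reproduced unit-agnostically as printed
(nominally 1e-3 mm^2/s).  One transcription normalization: the caudal FA
block prints the obvious misspelling "somaotsensory ctx secondary", which is
recorded here under the spelling used everywhere else, "somatosensory ctx
secondary", so that cross-site region intersections are well defined.
"""

from __future__ import annotations

import pandas as pd

from .stats import ComparisonTable

__all__ = ["GROUP_SIZES", "published_table", "SITES", "INDICES"]

SITES = ("rostral", "caudal")
INDICES = ("FA", "RD", "AD")

GROUP_SIZES = {"rostral": 5, "caudal": 8}

# rows: (region, contra_mean, contra_sd, ipsi_mean, ipsi_sd, arrow, p)
_ROWS: dict[tuple[str, str], list[tuple]] = {
    ("FA", "rostral"): [
        ("CA1 dorsal hippocampus", 0.336, 0.021, 0.410, 0.010, "↑", 0.001),
        ("central amygdala", 0.414, 0.044, 0.582, 0.033, "↑", 0.001),
        ("medial amygdala", 0.482, 0.059, 0.618, 0.013, "↑", 0.001),
        ("laterodorsal thalamus", 0.436, 0.068, 0.276, 0.042, "↓", 0.002),
        ("dorsomedial striatum", 0.368, 0.018, 0.414, 0.017, "↑", 0.003),
        ("lateral geniculate", 0.316, 0.024, 0.278, 0.011, "↓", 0.012),
        ("somatosensory ctx secondary", 0.220, 0.012, 0.246, 0.013, "↑", 0.013),
        ("lateral amygdala", 0.262, 0.036, 0.356, 0.055, "↑", 0.013),
        ("subiculum hippocampus", 0.298, 0.033, 0.344, 0.015, "↑", 0.021),
        ("nucleus brachium", 0.208, 0.042, 0.272, 0.039, "↑", 0.046),
    ],
    ("FA", "caudal"): [
        ("laterodorsal thalamus", 0.488, 0.050, 0.357, 0.060, "↓", 0.001),
        ("dentate gyrus hippocampus", 0.203, 0.016, 0.245, 0.021, "↑", 0.001),
        ("CA3 hippocampus ventral", 0.241, 0.046, 0.343, 0.047, "↑", 0.001),
        ("globus pallidus", 0.356, 0.047, 0.457, 0.047, "↑", 0.001),
        ("auditory ctx", 0.173, 0.031, 0.221, 0.024, "↑", 0.003),
        ("basal amygdala", 0.264, 0.014, 0.232, 0.021, "↓", 0.004),
        ("somatosensory ctx secondary", 0.186, 0.021, 0.216, 0.016, "↑", 0.007),
        ("somatosensory ctx primary", 0.208, 0.028, 0.242, 0.014, "↑", 0.007),
        ("temporal ctx", 0.196, 0.023, 0.230, 0.021, "↑", 0.008),
        ("insular ctx", 0.199, 0.019, 0.226, 0.018, "↑", 0.011),
        ("gustatory ctx", 0.250, 0.028, 0.288, 0.026, "↑", 0.013),
        ("paraventricular thalamic nuclei", 0.353, 0.037, 0.301, 0.036, "↓", 0.013),
        ("central amygdala", 0.320, 0.053, 0.418, 0.083, "↑", 0.013),
        ("medial geniculate", 0.260, 0.025, 0.288, 0.017, "↑", 0.018),
        ("medial septum", 0.356, 0.037, 0.400, 0.028, "↑", 0.019),
        ("lateral amygdala", 0.256, 0.030, 0.210, 0.040, "↓", 0.020),
        ("infralimbic ctx", 0.288, 0.047, 0.232, 0.040, "↓", 0.023),
        ("agranular insular ctx", 0.225, 0.019, 0.252, 0.025, "↑", 0.025),
        ("anterior cingulate ctx", 0.276, 0.037, 0.232, 0.034, "↓", 0.026),
        ("cortical amygdala", 0.256, 0.034, 0.300, 0.037, "↑", 0.026),
    ],
    ("RD", "rostral"): [
        ("CA1 dorsal hippocampus", 0.256, 0.022, 0.330, 0.007, "↑", 0.001),
        ("central amygdala", 0.316, 0.033, 0.492, 0.044, "↑", 0.001),
        ("medial amygdala", 0.394, 0.053, 0.540, 0.014, "↑", 0.001),
        ("laterodorsal thalamus", 0.388, 0.073, 0.210, 0.035, "↓", 0.001),
        ("dorsomedial striatum", 0.284, 0.015, 0.340, 0.024, "↑", 0.002),
        ("subiculum hippocampus", 0.232, 0.029, 0.286, 0.018, "↑", 0.008),
        ("lateral amygdala", 0.204, 0.027, 0.310, 0.063, "↑", 0.009),
        ("cochlear nucleus", 0.212, 0.028, 0.316, 0.081, "↑", 0.026),
        ("lateral geniculate", 0.234, 0.026, 0.200, 0.012, "↓", 0.030),
        ("nucleus brachium", 0.180, 0.027, 0.224, 0.032, "↑", 0.048),
    ],
    ("RD", "caudal"): [
        ("dentate gyrus hippocampus", 0.168, 0.012, 0.207, 0.018, "↑", 0.001),
        ("laterodorsal thalamus", 0.434, 0.061, 0.298, 0.064, "↓", 0.001),
        ("CA3 ventral hippocampus", 0.193, 0.041, 0.286, 0.048, "↑", 0.001),
        ("globus pallidus", 0.265, 0.039, 0.357, 0.054, "↑", 0.002),
        ("auditory ctx", 0.126, 0.023, 0.162, 0.015, "↑", 0.002),
        ("somatosensory ctx secondary", 0.134, 0.016, 0.158, 0.011, "↑", 0.003),
        ("gustatory ctx", 0.190, 0.017, 0.220, 0.021, "↑", 0.007),
        ("paraventricular thalamic nuclei", 0.326, 0.024, 0.286, 0.027, "↓", 0.007),
        ("insular ctx", 0.145, 0.014, 0.166, 0.013, "↑", 0.007),
        ("central amygdala", 0.245, 0.038, 0.340, 0.078, "↑", 0.008),
        ("somatosensory ctx primary", 0.158, 0.018, 0.180, 0.013, "↑", 0.011),
        ("cortical amygdala", 0.198, 0.029, 0.252, 0.045, "↑", 0.012),
        ("temporal ctx", 0.145, 0.021, 0.171, 0.015, "↑", 0.012),
        ("medial septum", 0.273, 0.034, 0.315, 0.026, "↑", 0.014),
        ("anterior cingulate ctx", 0.218, 0.029, 0.180, 0.027, "↓", 0.018),
        ("infralimbic ctx", 0.219, 0.039, 0.175, 0.032, "↓", 0.029),
        ("agranular insular ctx", 0.168, 0.016, 0.191, 0.024, "↑", 0.033),
        ("basal amygdala", 0.203, 0.014, 0.182, 0.020, "↓", 0.035),
        ("medial amygdala", 0.294, 0.042, 0.362, 0.072, "↑", 0.036),
        ("medial geniculate", 0.195, 0.023, 0.217, 0.017, "↑", 0.040),
        ("posterior amygdala", 0.273, 0.090, 0.388, 0.116, "↑", 0.042),
    ],
    ("AD", "rostral"): [
        ("central amygdala", 1.098, 0.074, 1.334, 0.088, "↑", 0.002),
        ("laterodorsal thalamus", 1.322, 0.149, 0.988, 0.099, "↓", 0.003),
        ("lateral amygdala", 1.136, 0.044, 1.360, 0.129, "↑", 0.006),
        ("raphe dorsal", 1.650, 0.139, 1.968, 0.199, "↑", 0.019),
        ("medial amygdala", 1.262, 0.101, 1.420, 0.068, "↑", 0.020),
        ("periaqueductal gray midbrain", 1.054, 0.063, 1.188, 0.091, "↑", 0.027),
        ("medial geniculate", 0.968, 0.085, 1.074, 0.023, "↑", 0.028),
        ("mediodorsal thalamus", 1.240, 0.063, 1.340, 0.071, "↑", 0.046),
    ],
    ("AD", "caudal"): [
        ("central amygdala", 1.071, 0.025, 1.221, 0.088, "↑", 0.001),
        ("mediodorsal thalamus", 1.164, 0.058, 1.280, 0.061, "↑", 0.002),
        ("medial amygdala", 1.204, 0.040, 1.327, 0.086, "↑", 0.002),
        ("dentate gyrus hippocampus", 1.101, 0.054, 1.235, 0.089, "↑", 0.003),
        ("laterodorsal thalamus", 1.410, 0.162, 1.172, 0.107, "↓", 0.004),
        ("subiculum hippocampus", 1.088, 0.027, 1.195, 0.085, "↑", 0.004),
        ("globus pallidus", 1.031, 0.060, 1.186, 0.114, "↑", 0.004),
        ("periaqueductal gray midbrain", 1.165, 0.073, 1.300, 0.105, "↑", 0.010),
        ("lateral posterior thalamus", 0.990, 0.079, 1.101, 0.072, "↑", 0.011),
        ("tenia tecta ctx", 1.178, 0.135, 1.403, 0.212, "↑", 0.023),
        ("cortical amygdala", 1.055, 0.076, 1.217, 0.165, "↑", 0.024),
        ("paraventricular n. hypo", 1.029, 0.087, 1.167, 0.155, "↑", 0.045),
    ],
}

_COLUMNS = ["region_name", "contra_mean", "contra_sd", "ipsi_mean", "ipsi_sd", "arrow", "p"]


def published_table(index: str, site: str) -> ComparisonTable:
    """Return one published summary table as a :class:`ComparisonTable`.

    Rows keep their printed order (already rank-ordered by significance) and
    carry the printed p-values; ``n`` is the group size for the site.
    """
    if index not in INDICES or site not in SITES:
        raise KeyError(f"no published table for ({index!r}, {site!r})")
    df = pd.DataFrame(_ROWS[(index, site)], columns=_COLUMNS)
    df["n"] = GROUP_SIZES[site]
    df["index"] = index
    return ComparisonTable(table=df, index=index, site=site, cutoff=0.05)
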