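"""Published summary statistics for the chicken Growth1 body-weight QTL.

These small tables were reported for an advanced intercross of the
Virginia body-weight selection lines (~2,930 phenotyped birds, 8-week
body weight normalized within sex-generation groups).  They serve as
inputs for internal-consistency reconstructions: recomputing ANOVA F
statistics from printed mean squares, and compact-letter displays from
printed per-genotype (mean, SD, count) triples.
"""

from __future__ import annotations

import numpy as np

#: Sequential ANOVA of the final stepwise model: term -> (mean square, F).
#: The final column is the printed p-value where given numerically.
STEPWISE_ANOVA = {
    "Sex": (1.47e7, 689.47),
    "Generation": (1.32e6, 61.72),
    "gga1_168m": (1.51e6, 70.80),
    "gga1_171v": (6.34e5, 29.65),
    "gga1_178v": (5.68e4, 2.66),
}

#: Printed p-value of the gga1_178v term in the final model.
STEPWISE_P_GGA1_178V = 0.1032

#: Residual degrees of freedom implied by the reported group counts.
STEPWISE_RESIDUAL_DF = 2900

#: Per-genotype normalized body weight: marker -> [(genotype, mean, SD, n, letter)].
GENOTYPE_GROUPS = {
    "gga1_168m": [
        ("RR", 0.1194, 0.9893, 1691, "a"),
        ("RA", -0.1183, 0.9861, 1075, "b"),
        ("AA", -0.4452, 0.8843, 164, "c"),
    ],
    "gga1_171m": [
        ("RR", 0.1979, 1.0384, 692, "a"),
        ("RA", 0.0010, 1.0069, 1552, "b"),
        ("AA", -0.2019, 0.8765, 686, "c"),
    ],
    "gga1_171v": [
        ("RR", -0.1751, 0.9158, 989, "a"),
        ("RA", 0.0375, 1.0125, 1538, "b"),
        ("AA", 0.2865, 1.0331, 403, "c"),
    ],
    "gga1_172v": [
        ("RR", -0.1306, 0.8909, 705, "a"),
        ("RA", 0.0004, 1.0117, 1574, "b"),
        ("AA", 0.1405, 1.0418, 651, "c"),
    ],
    "gga1_174v": [
        ("RR", 0.0770, 1.0208, 939, "a"),
        ("RA", -0.0050, 1.0139, 1509, "b"),
        ("AA", -0.1343, 0.8617, 482, "c"),
    ],
    "gga1_178v": [
        ("RR", 0.0638, 1.0719, 1071, "a"),
        ("RA", -0.0053, 0.9631, 1426, "a"),
        ("AA", -0.1404, 0.8803, 433, "b"),
    ],
}


def implied_residual_mean_square() -> float:
    """Residual mean square implied by the ANOVA table (mean of MS/F)."""
    return float(np.mean([ms / f for ms, f in STEPWISE_ANOVA.values()]))


def recomputed_f(term: str) -> float:
    """Term F recomputed from its printed mean square and the implied residual MS."""
    ms, _ = STEPWISE_ANOVA[term]
    return ms / implied_residual_mean_square()
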