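"""Variance-heterogeneity scan via the Brown-Forsythe test.

For each marker the phenotype (normalized within sex-generation cells
once per cohort, before the scan) is split by genotype class; the
absolute deviation from each class's median is analyzed by one-way
ANOVA.  A large F indicates genotype classes differing in spread — a
vQTL signature that can arise from epistasis, incomplete LD with
multiple causal alleles, or GxE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeMatrix, SampleRecord
from .gwas import _marker_column, _phenotype_vector


@dataclass
class VarianceTestResult:
    marker_id: str
    group_medians: dict[int, float] = field(default_factory=dict)
    group_mean_absdev: dict[int, float] = field(default_factory=dict)
    f_bf: float = float("nan")
    df_between: int = 0
    df_within: int = 0
    pvalue: float = float("nan")
    neglog10p: float = float("nan")
    n_used: int = 0
    flag: str | None = None


def brown_forsythe(
    y_norm: np.ndarray,
    geno: np.ndarray,
    marker_id: str = "",
    min_class_n: int = 10,
) -> VarianceTestResult:
    """Brown-Forsythe (Levene-with-median) test of variance equality.

    Classes with fewer than ``min_class_n`` non-missing values are
    dropped (degrees of freedom adjust accordingly).  The median of an
    even-sized class is the midpoint of the two central order
    statistics.  If all absolute deviations are zero the result is
    flagged degenerate with p = 1.
    """
    y = np.asarray(y_norm, dtype=float)
    g = np.asarray(geno)
    keep = np.isfinite(y) & (g != MISSING)
    y, g = y[keep], g[keep]
    groups, medians, absdev = [], {}, {}
    for cls in (0, 1, 2):
        vals = y[g == cls]
        if len(vals) < min_class_n:
            continue
        med = float(np.median(vals))
        medians[cls] = med
        dev = np.abs(vals - med)
        absdev[cls] = float(dev.mean())
        groups.append(dev)
    n_used = int(sum(len(d) for d in groups))
    if len(groups) < 2:
        return VarianceTestResult(
            marker_id, medians, absdev, n_used=n_used, flag="fewer_than_2_classes"
        )
    k = len(groups)
    df_b, df_w = k - 1, n_used - k
    alldev = np.concatenate(groups)
    grand = alldev.mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in groups)
    ss_within = sum(float(np.sum((d - d.mean()) ** 2)) for d in groups)
    if ss_within == 0 and ss_between == 0:
        return VarianceTestResult(
            marker_id, medians, absdev, 0.0, df_b, df_w, 1.0, 0.0, n_used, "degenerate"
        )
    if ss_within == 0:
        return VarianceTestResult(
            marker_id, medians, absdev, float("inf"), df_b, df_w, 0.0, float("inf"),
            n_used, "degenerate",
        )
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return VarianceTestResult(
        marker_id,
        medians,
        absdev,
        float(f),
        df_b,
        df_w,
        p,
        float(-np.log10(p)) if p > 0 else float("inf"),
        n_used,
    )


def vgwas_scan(
    y_norm,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    markers: Sequence[str] | None = None,
    min_class_n: int = 10,
) -> list[VarianceTestResult]:
    """Brown-Forsythe test over the panel on pre-normalized phenotypes."""
    markers = list(markers) if markers is not None else list(genotypes.marker_ids)
    yv = _phenotype_vector(y_norm, samples)
    sample_idx = [genotypes.sample_index(s.sample_id) for s in samples]
    calls = genotypes.calls[sample_idx]
    pos = {m: j for j, m in enumerate(genotypes.marker_ids)}
    return [
        brown_forsythe(yv, calls[:, pos[m]], marker_id=m, min_class_n=min_class_n)
        for m in markers
    ]


def vgwas_frame(results: Sequence[VarianceTestResult]):
    """Tabulate vGWAS results, including per-class medians."""
    import pandas as pd

    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in results],
            "n": [r.n_used for r in results],
            "f_bf": [r.f_bf for r in results],
            "df_between": [r.df_between for r in results],
            "df_within": [r.df_within for r in results],
            "p": [r.pvalue for r in results],
            "neglog10p": [r.neglog10p for r in results],
            "median_RR": [r.group_medians.get(0, np.nan) for r in results],
            "median_RA": [r.group_medians.get(1, np.nan) for r in results],
            "median_AA": [r.group_medians.get(2, np.nan) for r in results],
            "flag": [r.flag or "" for r in results],
        }
    )
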