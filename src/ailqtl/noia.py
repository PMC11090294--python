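"""NOIA orthogonal decomposition of genetic effects and epistasis scans.

The statistical NOIA parameterization builds, for each locus, additive
and dominance design columns that are orthogonal under the *observed*
genotype frequencies (p11, p12, p22 for ALT counts 0, 1, 2):

    x_a(g) = g - (p12 + 2 p22)
    x_d    = (-2 p12 p22,  4 p11 p22,  -2 p11 p12) / (p11 + p22 - (p11 - p22)^2)

so that sum p g(x_a) = sum p g(x_d) = sum p x_a x_d = 0.  Effect
estimates are therefore invariant to dropping other terms (in-sample),
and the intercept equals the frequency-weighted mean genotype value —
the reference point R.  Two-locus designs are Kronecker combinations
of the single-locus rows, giving aa/ad/da/dd interaction columns.

Genotype-stratified conditional scans re-run the marker scan within
each genotype class of a conditioning locus, the direct way to see one
locus's signal switched off by another's genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, SampleRecord
from .gwas import AssociationResult, gwas_scan, _marker_column, _phenotype_vector


@dataclass
class LocusFrequencies:
    """Genotype frequencies for ALT counts 0, 1, 2."""

    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        total = self.p11 + self.p12 + self.p22
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if min(self.p11, self.p12, self.p22) < 0:
            raise ValueError("negative genotype frequency")

    @classmethod
    def from_genotypes(cls, calls: np.ndarray) -> "LocusFrequencies":
        calls = np.asarray(calls)
        calls = calls[calls != MISSING]
        if len(calls) == 0:
            raise ValueError("no non-missing calls")
        n = len(calls)
        c = [float(np.sum(calls == g)) for g in (0, 1, 2)]
        p11, p12 = c[0] / n, c[1] / n
        return cls(p11, p12, 1.0 - p11 - p12)

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22])


@dataclass
class NOIADesign:
    """Per-genotype design rows over (mean, additive, dominance) columns."""

    rows: np.ndarray  # (3, k) or (9, k)
    columns: list[str]
    frequencies: tuple[LocusFrequencies, ...]
    flag: str | None = None


@dataclass
class NOIAEffects:
    """Estimated genetic effects from a NOIA least-squares fit."""

    markers: list[str]
    effects: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    reference_point: float
    fitted_values: np.ndarray | None  # genotype-grid predictions (3 or 9)
    n_used: int
    inestimable: list[str] = field(default_factory=list)


def single_locus_design(freq: LocusFrequencies) -> NOIADesign:
    """Frequency-adjusted additive/dominance design for one locus.

    If a genotype class is absent (the dominance denominator vanishes)
    an additive-only design is returned with an explicit flag.
    """
    p11, p12, p22 = freq.p11, freq.p12, freq.p22
    if sum(p > 0 for p in (p11, p12, p22)) < 2:
        raise ValueError("need at least two genotype classes with positive frequency")
    xa = np.arange(3) - (p12 + 2 * p22)
    denom = p11 + p22 - (p11 - p22) ** 2
    if denom <= 1e-12 or min(p11, p12, p22) == 0:
        rows = np.column_stack([np.ones(3), xa])
        return NOIADesign(rows, ["mean", "a"], (freq,), flag="additive_only")
    xd = np.array([-2 * p12 * p22, 4 * p11 * p22, -2 * p11 * p12]) / denom
    rows = np.column_stack([np.ones(3), xa, xd])
    return NOIADesign(rows, ["mean", "a", "d"], (freq,))


def reference_point(freq: LocusFrequencies, genotype_values: Sequence[float]) -> float:
    """Frequency-weighted mean genotype value R."""
    g = np.asarray(genotype_values, dtype=float)
    if g.shape != (3,):
        raise ValueError("expected three genotype values")
    return float(freq.as_array() @ g)


def two_locus_design(freq_a: LocusFrequencies, freq_b: LocusFrequencies) -> NOIADesign:
    """Kronecker two-locus design: 9 joint-genotype rows.

    Row order is (gA, gB) with gB varying fastest; columns are
    (mean, a_A, d_A, a_B, d_B, aa, ad, da, dd) where ad = a_A x d_B.
    Degenerate loci reduce the column set with a flag.
    """
    da, db = single_locus_design(freq_a), single_locus_design(freq_b)
    flag = None
    if da.flag or db.flag:
        flag = "reduced_columns"
    cols_a = da.columns[1:]  # effect columns beyond the mean
    cols_b = db.columns[1:]
    names = ["mean"]
    names += [f"{c}_A" for c in cols_a]
    names += [f"{c}_B" for c in cols_b]
    names += [f"{ca}{cb}" for ca in cols_a for cb in cols_b]
    rows = np.zeros((9, len(names)))
    for i in range(3):
        for j in range(3):
            r = [1.0]
            r += [da.rows[i, 1 + k] for k in range(len(cols_a))]
            r += [db.rows[j, 1 + k] for k in range(len(cols_b))]
            r += [
                da.rows[i, 1 + ka] * db.rows[j, 1 + kb]
                for ka in range(len(cols_a))
                for kb in range(len(cols_b))
            ]
            rows[i * 3 + j] = r
    return NOIADesign(rows, names, (freq_a, freq_b), flag)


def fit_noia(
    y_norm,
    genotypes: GenotypeMatrix,
    markers: Sequence[str],
    samples: Sequence[SampleRecord] | None = None,
    order: int = 2,
) -> NOIAEffects:
    """Least-squares NOIA fit over 2..k loci with pairwise interactions.

    The sample-level design is built from each locus's observed
    genotype frequencies; with ``order=2`` every marker pair
    contributes aa/ad/da/dd columns, with ``order=1`` only main
    effects enter.  Effects whose columns are collinear (e.g. empty
    joint genotype cells) are flagged inestimable and dropped from the
    fit.  The phenotype should already have sex/generation removed by
    within-cell normalization.
    """
    markers = list(markers)
    if len(markers) < 1:
        raise ValueError("need at least one marker")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if samples is not None:
        yv = _phenotype_vector(y_norm, samples)
        idx = [genotypes.sample_index(s.sample_id) for s in samples]
    else:
        yv = np.asarray(y_norm, dtype=float)
        if len(yv) != genotypes.n_samples:
            raise ValueError("y length != n_samples")
        idx = list(range(genotypes.n_samples))
    calls = genotypes.calls[idx][:, [genotypes.marker_index(m) for m in markers]]
    use = np.isfinite(yv) & (calls != MISSING).all(axis=1)
    yy = yv[use]
    calls = calls[use]
    n = len(yy)

    designs = {}
    for k, m in enumerate(markers):
        designs[m] = single_locus_design(LocusFrequencies.from_genotypes(calls[:, k]))

    col_names = ["R"]
    col_data = [np.ones(n)]
    for k, m in enumerate(markers):
        d = designs[m]
        g = calls[:, k]
        for ci, cname in enumerate(d.columns[1:], start=1):
            col_names.append(f"{cname}_{m}")
            col_data.append(d.rows[g, ci])
    if order == 2:
        for (ka, ma), (kb, mb) in combinations(enumerate(markers), 2):
            da, db = designs[ma], designs[mb]
            ga, gb = calls[:, ka], calls[:, kb]
            for ia, ca in enumerate(da.columns[1:], start=1):
                for ib, cb in enumerate(db.columns[1:], start=1):
                    col_names.append(f"{ca}{cb}_{ma}:{mb}")
                    col_data.append(da.rows[ga, ia] * db.rows[gb, ib])
    x = np.column_stack(col_data)

    # detect collinear columns via pivoted QR; flag them inestimable
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > 1e-9 * max(diag.max(), 1.0)))
    keep = sorted(piv[:rank])
    if 0 not in keep:  # always keep the mean column
        keep = [0] + keep[:-1]
    inestimable = [col_names[j] for j in range(len(col_names)) if j not in keep]
    xk = x[:, keep]
    beta, rss, _, _ = np.linalg.lstsq(xk, yy, rcond=None)
    rss = float(rss[0]) if len(rss) else float(np.sum((yy - xk @ beta) ** 2))
    df = n - xk.shape[1]
    effects, se, pvals = {}, {}, {}
    if df > 0 and rss > 0:
        sigma2 = rss / df
        xtx_inv = np.linalg.inv(xk.T @ xk)
        for i, j in enumerate(keep):
            name = col_names[j]
            effects[name] = float(beta[i])
            se[name] = float(np.sqrt(sigma2 * xtx_inv[i, i]))
            t = beta[i] / se[name] if se[name] > 0 else np.inf
            pvals[name] = float(2.0 * stats.t.sf(abs(t), df))
    else:
        for i, j in enumerate(keep):
            name = col_names[j]
            effects[name] = float(beta[i])
            se[name] = 0.0
            pvals[name] = 0.0

    fitted = None
    if len(markers) == 1:
        d = designs[markers[0]]
        fitted = d.rows @ np.array([effects.get(_nm(c, markers[0]), 0.0) for c in d.columns])
    elif len(markers) == 2 and order == 2:
        d2 = two_locus_design(designs[markers[0]].frequencies[0], designs[markers[1]].frequencies[0])
        vec = []
        for c in d2.columns:
            vec.append(effects.get(_joint_nm(c, markers[0], markers[1]), 0.0))
        fitted = d2.rows @ np.array(vec)
    return NOIAEffects(
        markers, effects, se, pvals, effects.get("R", float("nan")), fitted, n, inestimable
    )


def _nm(col: str, marker: str) -> str:
    return "R" if col == "mean" else f"{col}_{marker}"


def _joint_nm(col: str, ma: str, mb: str) -> str:
    if col == "mean":
        return "R"
    if col.endswith("_A"):
        return f"{col[:-2]}_{ma}"
    if col.endswith("_B"):
        return f"{col[:-2]}_{mb}"
    return f"{col}_{ma}:{mb}"


INTERACTION_TYPES = ("aa", "ad", "da", "dd")


def pairwise_interaction_network(
    y_norm,
    genotypes: GenotypeMatrix,
    markers: Sequence[str],
    samples: Sequence[SampleRecord] | None = None,
) -> pd.DataFrame:
    """NOIA fit on every marker pair; one row per interaction effect.

    Columns: marker_i, marker_j, type (aa/ad/da/dd), estimate, se, p,
    p_bonferroni (over all emitted interaction tests).  A hub locus
    shows up as the marker participating in the most significant edges.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    rows = []
    for ma, mb in combinations(markers, 2):
        fit = fit_noia(y_norm, genotypes, [ma, mb], samples=samples, order=2)
        for t in INTERACTION_TYPES:
            name = f"{t}_{ma}:{mb}"
            if name in fit.effects:
                rows.append(
                    {
                        "marker_i": ma,
                        "marker_j": mb,
                        "type": t,
                        "estimate": fit.effects[name],
                        "se": fit.se[name],
                        "p": fit.pvalues[name],
                    }
                )
            elif name in fit.inestimable:
                rows.append(
                    {
                        "marker_i": ma, "marker_j": mb, "type": t,
                        "estimate": np.nan, "se": np.nan, "p": np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    n_tests = int(df["p"].notna().sum())
    df["p_bonferroni"] = np.minimum(df["p"] * n_tests, 1.0)
    return df


@dataclass
class ConditionalScanResult:
    conditioning_marker: str
    strata: dict[int, list[AssociationResult]]
    stratum_n: dict[int, int]
    omitted_strata: list[int]
    grid_mean: np.ndarray | None = None  # 3x3, rows = focal genotype
    grid_sd: np.ndarray | None = None
    grid_count: np.ndarray | None = None
    focal_marker: str | None = None


def conditional_scan(
    y_norm,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    conditioning_marker: str,
    scan_markers: Sequence[str] | None = None,
    focal_marker: str | None = None,
    min_class_n: int = 10,
    refit_covariates: bool = False,
) -> ConditionalScanResult:
    """Genotype-stratified association scan.

    Samples are split by genotype (0/1/2) at the conditioning marker
    and the single-marker scan re-run within each stratum.  With
    pre-normalized phenotypes the within-stratum model is intercept +
    marker; ``refit_covariates=True`` refits sex/generation inside each
    stratum instead.  Strata below ``min_class_n`` are omitted with a
    flag.  If ``focal_marker`` is given, the two-locus 3x3 grid of
    (mean, SD, count) of the phenotype is also reported.
    """
    yv = _phenotype_vector(y_norm, samples)
    cond = _marker_column(genotypes, samples, conditioning_marker)
    covs = ("sex", "generation") if refit_covariates else ()
    strata: dict[int, list[AssociationResult]] = {}
    stratum_n: dict[int, int] = {}
    omitted = []
    usable = np.isfinite(yv) & (cond != MISSING)
    for g in (0, 1, 2):
        mask = usable & (cond == g)
        stratum_n[g] = int(mask.sum())
        if stratum_n[g] < min_class_n:
            omitted.append(g)
            continue
        sub = [s for s, m in zip(samples, mask) if m]
        strata[g] = gwas_scan(yv[mask], sub, genotypes, markers=scan_markers, covariates=covs)
    if len(strata) < 2:
        raise ValueError(
            f"conditioning marker {conditioning_marker} has fewer than 2 usable classes"
        )
    grid_mean = grid_sd = grid_count = None
    if focal_marker is not None:
        focal = _marker_column(genotypes, samples, focal_marker)
        grid_mean = np.full((3, 3), np.nan)
        grid_sd = np.full((3, 3), np.nan)
        grid_count = np.zeros((3, 3), dtype=int)
        for i in range(3):
            for j in range(3):
                vals = yv[usable & (focal == i) & (cond == j)]
                grid_count[i, j] = len(vals)
                if len(vals):
                    grid_mean[i, j] = vals.mean()
                if len(vals) > 1:
                    grid_sd[i, j] = vals.std(ddof=1)
    return ConditionalScanResult(
        conditioning_marker, strata, stratum_n, omitted, grid_mean, grid_sd, grid_count,
        focal_marker,
    )
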