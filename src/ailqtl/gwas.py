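"""Single-marker association scans with sex/generation fixed effects.

The core model is ordinary least squares of body weight on an intercept,
a binary sex indicator, generation as an unordered factor, optional
conditioning-marker allele counts, and the tested marker's ALT-allele
count.  The per-marker effect is tested with a two-sided t-test at the
residual degrees of freedom.  Scans use Frisch-Waugh residualization on
the shared covariate block, which is numerically identical to the full
per-marker fit; a brute-force normal-equations fit is kept as the slow
path for markers with missing calls.

Also here: within sex-generation-cell phenotype normalization, stepwise
marker selection, sequential (type-I) ANOVA reporting, genotype-group
summaries and LSD compact-letter grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, MarkerMap, SampleRecord

GENOTYPE_LABELS = {0: "RR", 1: "RA", 2: "AA"}

_RANK_TOL = 1e-6  # relative tolerance for declaring a residualized column null


@dataclass
class AssociationResult:
    """Per-marker output of the linear-model scan."""

    marker_id: str
    effect: float = float("nan")
    se: float = float("nan")
    intercept: float = float("nan")
    covariate_effects: dict[str, float] = field(default_factory=dict)
    stat: float = float("nan")
    pvalue: float = float("nan")
    neglog10p: float = float("nan")
    n_used: int = 0
    residual_variance: float = float("nan")
    flag: str | None = None


@dataclass
class AnovaRow:
    term: str
    df: int
    mean_square: float
    f_value: float
    pvalue: float


@dataclass
class GroupSummary:
    genotype: str
    mean: float
    sd: float
    count: int
    letter: str = ""


@dataclass
class StepwiseFit:
    """Handle to the final stepwise model, consumable by :func:`anova_table`."""

    y: np.ndarray
    samples: list[SampleRecord]
    genotypes: GenotypeMatrix
    selected: list[str]
    covariates: tuple[str, ...]


# ---------------------------------------------------------------------------
# Phenotype normalization
# ---------------------------------------------------------------------------


def normalize_by_group(samples: Sequence[SampleRecord]) -> np.ndarray:
    """Z-score body weight within each (sex, generation) cell.

    Returns a vector aligned with ``samples``; entries for samples with
    missing bw8 are NaN.  Uses the n-1 sample SD, so each cell has mean
    0 and SD 1.  Cells with fewer than two phenotyped samples or zero
    SD are errors (the cell is named in the message).
    """
    bw8 = np.array([np.nan if s.bw8 is None else s.bw8 for s in samples], dtype=float)
    keys = [(s.sex, s.generation) for s in samples]
    out = np.full(len(samples), np.nan)
    for cell in sorted(set(k for k, w in zip(keys, bw8) if np.isfinite(w))):
        mask = np.array([k == cell for k in keys]) & np.isfinite(bw8)
        vals = bw8[mask]
        if len(vals) < 2:
            raise ValueError(f"cell sex={cell[0]} generation={cell[1]} has < 2 phenotyped samples")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cell sex={cell[0]} generation={cell[1]} has zero SD")
        out[mask] = (vals - vals.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------


def _covariate_matrix(
    samples: Sequence[SampleRecord], covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + requested covariate columns (sex indicator, generation dummies)."""
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    if "sex" in covariates and len({s.sex for s in samples}) > 1:
        cols.append(np.array([1.0 if s.sex == "M" else 0.0 for s in samples]))
        names.append("sex[M]")
    if "generation" in covariates:
        gens = sorted({s.generation for s in samples})
        for g in gens[1:]:  # first level is the baseline
            cols.append(np.array([1.0 if s.generation == g else 0.0 for s in samples]))
            names.append(f"generation[{g}]")
    return np.column_stack(cols), names


def _phenotype_vector(y, samples: Sequence[SampleRecord]) -> np.ndarray:
    if y is None:
        return np.array([np.nan if s.bw8 is None else s.bw8 for s in samples], dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != len(samples):
        raise ValueError("phenotype vector length != number of samples")
    return y


def _marker_column(genotypes: GenotypeMatrix, samples, marker: str) -> np.ndarray:
    idx = [genotypes.sample_index(s.sample_id) for s in samples]
    return genotypes.column(marker)[idx].astype(float)


# ---------------------------------------------------------------------------
# Single-marker fit (slow, exact path)
# ---------------------------------------------------------------------------


def fit_marker_lm(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    marker: str,
    conditioning: Sequence[str] | None = None,
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> AssociationResult:
    """OLS of phenotype on covariates (+ conditioning markers) + marker.

    Cases with missing phenotype or any needed genotype are dropped for
    this marker.  Monomorphic markers are skipped with a reason;
    rank-deficient designs (e.g. the marker collinear with a
    conditioning marker) are flagged with an undefined effect; perfect
    fits are flagged ``degenerate`` with p = 0.
    """
    conditioning = list(conditioning or [])
    yv = _phenotype_vector(y, samples)
    a = _marker_column(genotypes, samples, marker)
    cond_cols = [_marker_column(genotypes, samples, c) for c in conditioning]
    use = np.isfinite(yv) & (a != MISSING)
    for cc in cond_cols:
        use &= cc != MISSING
    n_used = int(use.sum())
    if n_used == 0 or len(np.unique(a[use])) < 2:
        return AssociationResult(marker, n_used=n_used, flag="monomorphic")

    sub = [s for s, u in zip(samples, use) if u]
    x0, names = _covariate_matrix(sub, covariates)
    x = np.column_stack([x0] + [cc[use] for cc in cond_cols] + [a[use]])
    names = names + conditioning + [marker]
    beta, rss, rank, _ = np.linalg.lstsq(x, yv[use], rcond=None)
    if rank < x.shape[1]:
        return AssociationResult(marker, n_used=n_used, flag="rank_deficient")
    rss = float(rss[0]) if len(rss) else float(np.sum((yv[use] - x @ beta) ** 2))
    df = n_used - x.shape[1]
    if df <= 0:
        return AssociationResult(marker, n_used=n_used, flag="zero_residual_df")
    yss = float(np.sum((yv[use] - yv[use].mean()) ** 2))
    xtx_inv = np.linalg.inv(x.T @ x)
    covariate_effects = dict(zip(names[1:-1], beta[1:-1]))
    if rss <= max(yss, 1.0) * 1e-12:
        return AssociationResult(
            marker,
            effect=float(beta[-1]),
            se=0.0,
            intercept=float(beta[0]),
            covariate_effects=covariate_effects,
            stat=float("inf"),
            pvalue=0.0,
            neglog10p=float("inf"),
            n_used=n_used,
            residual_variance=0.0,
            flag="degenerate",
        )
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    t = float(beta[-1] / se)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(
        marker,
        effect=float(beta[-1]),
        se=se,
        intercept=float(beta[0]),
        covariate_effects=covariate_effects,
        stat=t,
        pvalue=p,
        neglog10p=float(-np.log10(p)) if p > 0 else float("inf"),
        n_used=n_used,
        residual_variance=float(sigma2),
    )


# ---------------------------------------------------------------------------
# Scan (fast residualized path)
# ---------------------------------------------------------------------------


def gwas_scan(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    markers: Sequence[str] | None = None,
    conditioning: Sequence[str] | None = None,
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> list[AssociationResult]:
    """Apply the single-marker model over the panel, preserving order.

    Markers without missing calls (over the scan's complete cases) are
    fitted via residualization on the shared covariate block — exactly
    equivalent to the full OLS fit; markers with missing calls fall
    back to the per-marker fit.  Scan results carry effect, se, t, p
    and n; intercept/covariate estimates are filled by the per-marker
    path only.
    """
    conditioning = list(conditioning or [])
    markers = list(markers) if markers is not None else list(genotypes.marker_ids)
    yv = _phenotype_vector(y, samples)
    cond_cols = [_marker_column(genotypes, samples, c) for c in conditioning]
    use = np.isfinite(yv)
    for cc in cond_cols:
        use &= cc != MISSING
    sub = [s for s, u in zip(samples, use) if u]
    n_used = len(sub)
    if n_used == 0:
        raise ValueError("no usable samples for scan")

    x0, _ = _covariate_matrix(sub, covariates)
    if cond_cols:
        x0 = np.column_stack([x0] + [cc[use] for cc in cond_cols])
    q, _ = np.linalg.qr(x0)
    p0 = int(np.linalg.matrix_rank(x0))
    yr = yv[use] - q @ (q.T @ yv[use])
    yrss = float(yr @ yr)
    df = n_used - p0 - 1

    sample_idx = [genotypes.sample_index(s.sample_id) for s in samples]
    calls = genotypes.calls[sample_idx][use]
    marker_pos = {m: j for j, m in enumerate(genotypes.marker_ids)}

    results: list[AssociationResult] = []
    chunk = 512
    fast, slow = [], []
    for m in markers:
        col = calls[:, marker_pos[m]]
        if np.any(col == MISSING):
            slow.append(m)
            fast.append(None)
        else:
            fast.append(m)
    for start in range(0, len(markers), chunk):
        block = markers[start : start + chunk]
        gcols = np.column_stack(
            [
                calls[:, marker_pos[m]].astype(float) if fast[start + k] else np.zeros(n_used)
                for k, m in enumerate(block)
            ]
        )
        gr = gcols - q @ (q.T @ gcols)
        den = np.einsum("ij,ij->j", gr, gr)
        num = gr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / den
            rss = yrss - beta * num
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            se = np.sqrt(sigma2 / den)
            t = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        for k, m in enumerate(block):
            if fast[start + k] is None:
                results.append(
                    fit_marker_lm(y, samples, genotypes, m, conditioning, covariates)
                )
                continue
            col = calls[:, marker_pos[m]]
            if col.min() == col.max():
                results.append(AssociationResult(m, n_used=n_used, flag="monomorphic"))
            elif den[k] <= _RANK_TOL * n_used:
                results.append(AssociationResult(m, n_used=n_used, flag="rank_deficient"))
            elif rss[k] <= max(yrss, 1.0) * 1e-12:
                results.append(
                    AssociationResult(
                        m, effect=float(beta[k]), se=0.0, stat=float("inf"),
                        pvalue=0.0, neglog10p=float("inf"), n_used=n_used,
                        residual_variance=0.0, flag="degenerate",
                    )
                )
            else:
                p = float(pvals[k])
                results.append(
                    AssociationResult(
                        m,
                        effect=float(beta[k]),
                        se=float(se[k]),
                        stat=float(t[k]),
                        pvalue=p,
                        neglog10p=float(-np.log10(p)) if p > 0 else float("inf"),
                        n_used=n_used,
                        residual_variance=float(sigma2[k]),
                    )
                )
    return results


def scan_frame(results: Sequence[AssociationResult], markers: MarkerMap | None = None) -> pd.DataFrame:
    """Tabulate scan results (optionally with coordinates) for writing."""
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in results],
            "n": [r.n_used for r in results],
            "effect": [r.effect for r in results],
            "se": [r.se for r in results],
            "stat": [r.stat for r in results],
            "p": [r.pvalue for r in results],
            "neglog10p": [r.neglog10p for r in results],
            "flag": [r.flag or "" for r in results],
        }
    )
    if markers is not None:
        coord = markers.to_frame().set_index("marker_id")
        df.insert(1, "chrom", coord["chrom"].reindex(df["marker_id"]).to_numpy())
        df.insert(2, "pos", coord["pos"].reindex(df["marker_id"]).to_numpy())
    return df


def bonferroni_line(n_tests: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected genome-wide threshold (for plots)."""
    return float(-np.log10(alpha / n_tests))


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------


def stepwise_select(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    candidate_markers: Sequence[str],
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    criterion: str = "pvalue",
    covariates: tuple[str, ...] = ("sex", "generation"),
    max_iter: int = 50,
) -> StepwiseFit:
    """Forward selection / backward elimination over candidate markers.

    Sex and generation are always retained.  With ``criterion='pvalue'``
    a marker enters when its added-last p-value is below ``alpha_in``
    and leaves when its fitted-jointly p-value exceeds ``alpha_out``;
    with ``criterion='aic'`` steps are taken while they lower the AIC.
    Deterministic: ties break by smaller p then lower marker position.
    """
    if criterion not in ("pvalue", "aic"):
        raise ValueError("criterion must be 'pvalue' or 'aic'")
    candidates = list(candidate_markers)
    if not candidates:
        raise ValueError("no candidate markers")
    selected: list[str] = []

    def _tie_key(m, p):
        return (p, genotypes.marker_index(m))

    def _aic(sel):
        res = _joint_fit(y, samples, genotypes, sel, covariates)
        n = res["n"]
        return n * np.log(res["rss"] / n) + 2 * (res["rank"] + 1)

    for _ in range(max_iter):
        changed = False
        # forward
        pool = [m for m in candidates if m not in selected]
        if pool:
            entries = []
            for m in pool:
                r = fit_marker_lm(y, samples, genotypes, m, conditioning=selected, covariates=covariates)
                if r.flag in ("monomorphic", "rank_deficient", "zero_residual_df"):
                    continue
                entries.append((m, r.pvalue))
            if entries:
                if criterion == "pvalue":
                    best = min(entries, key=lambda e: _tie_key(*e))
                    if best[1] < alpha_in:
                        selected.append(best[0])
                        changed = True
                else:
                    base = _aic(selected)
                    scored = sorted(
                        ((m, _aic(selected + [m])) for m, _ in entries),
                        key=lambda e: (e[1], genotypes.marker_index(e[0])),
                    )
                    if scored and scored[0][1] < base:
                        selected.append(scored[0][0])
                        changed = True
        # backward
        if len(selected) > (0 if criterion == "aic" else 1):
            joint = _joint_fit(y, samples, genotypes, selected, covariates)
            if criterion == "pvalue":
                worst = max(
                    ((m, joint["marker_p"][m]) for m in selected),
                    key=lambda e: (e[1], -genotypes.marker_index(e[0])),
                )
                if worst[1] > alpha_out:
                    selected.remove(worst[0])
                    changed = True
            else:
                base = _aic(selected)
                scored = sorted(
                    ((m, _aic([s for s in selected if s != m])) for m in selected),
                    key=lambda e: (e[1], genotypes.marker_index(e[0])),
                )
                if scored and scored[0][1] < base:
                    selected.remove(scored[0][0])
                    changed = True
        if not changed:
            break
    return StepwiseFit(_phenotype_vector(y, samples), list(samples), genotypes, selected, covariates)


def _joint_fit(y, samples, genotypes, selected, covariates):
    """Fit covariates + all selected markers jointly; per-marker t-test p."""
    yv = _phenotype_vector(y, samples)
    cols = [_marker_column(genotypes, samples, m) for m in selected]
    use = np.isfinite(yv)
    for c in cols:
        use &= c != MISSING
    sub = [s for s, u in zip(samples, use) if u]
    x0, _ = _covariate_matrix(sub, covariates)
    x = np.column_stack([x0] + [c[use] for c in cols]) if cols else x0
    beta, rss, rank, _ = np.linalg.lstsq(x, yv[use], rcond=None)
    n = int(use.sum())
    rss = float(rss[0]) if len(rss) else float(np.sum((yv[use] - x @ beta) ** 2))
    df = n - x.shape[1]
    marker_p = {}
    if cols and df > 0 and rank == x.shape[1] and rss > 0:
        xtx_inv = np.linalg.inv(x.T @ x)
        sigma2 = rss / df
        for k, m in enumerate(selected):
            j = x0.shape[1] + k
            t = beta[j] / np.sqrt(sigma2 * xtx_inv[j, j])
            marker_p[m] = float(2.0 * stats.t.sf(abs(t), df))
    else:
        marker_p = {m: 1.0 for m in selected}
    return {"rss": rss, "rank": int(rank), "n": n, "marker_p": marker_p}


# ---------------------------------------------------------------------------
# Sequential ANOVA
# ---------------------------------------------------------------------------


def anova_table(fit: StepwiseFit) -> list[AnovaRow]:
    """Sequential (type-I) ANOVA of the final model, one fitted model.

    Terms enter in the order sex, generation, then markers in selection
    order; each F is the term's mean square over the single residual
    mean square of the full fit.
    """
    return sequential_anova(
        fit.y, fit.samples, fit.genotypes, fit.selected, covariates=fit.covariates
    )


def sequential_anova(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    markers: Sequence[str],
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> list[AnovaRow]:
    yv = _phenotype_vector(y, samples)
    cols = [_marker_column(genotypes, samples, m) for m in markers]
    use = np.isfinite(yv)
    for c in cols:
        use &= c != MISSING
    sub = [s for s, u in zip(samples, use) if u]
    yy = yv[use]
    n = len(yy)

    terms: list[tuple[str, np.ndarray]] = []
    ones = np.ones((n, 1))
    if "sex" in covariates:
        terms.append(("Sex", np.array([[1.0 if s.sex == "M" else 0.0] for s in sub])))
    if "generation" in covariates:
        gens = sorted({s.generation for s in sub})
        gmat = np.column_stack(
            [[1.0 if s.generation == g else 0.0 for s in sub] for g in gens[1:]]
        ) if len(gens) > 1 else np.empty((n, 0))
        terms.append(("Generation", gmat))
    for m, c in zip(markers, cols):
        terms.append((m, c[use].reshape(-1, 1)))

    x = ones
    rss_prev = float(np.sum((yy - yy.mean()) ** 2))
    rank_prev = 1
    rows: list[AnovaRow] = []
    deltas: list[tuple[str, float, int]] = []
    for name, block in terms:
        x = np.column_stack([x, block])
        q, r = np.linalg.qr(x)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())))
        resid = yy - q[:, :] @ (q.T @ yy)
        rss = float(resid @ resid)
        deltas.append((name, rss_prev - rss, rank - rank_prev))
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    for name, ss, df in deltas:
        if df == 0:
            rows.append(AnovaRow(name, 0, float("nan"), float("nan"), float("nan")))
            continue
        ms = ss / df
        f = ms / ms_resid
        rows.append(AnovaRow(name, df, ms, f, float(stats.f.sf(f, df, df_resid))))
    rows.append(AnovaRow("Residuals", df_resid, ms_resid, float("nan"), float("nan")))
    return rows


# ---------------------------------------------------------------------------
# Genotype-group summaries and LSD letters
# ---------------------------------------------------------------------------


def genotype_group_summary(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    marker: str,
) -> list[GroupSummary]:
    """Per-genotype mean, sample SD and count of the (normalized) phenotype."""
    yv = _phenotype_vector(y, samples)
    a = _marker_column(genotypes, samples, marker)
    out = []
    for g in (0, 1, 2):
        vals = yv[np.isfinite(yv) & (a == g)]
        if len(vals) == 0:
            continue
        out.append(
            GroupSummary(
                GENOTYPE_LABELS[g],
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                int(len(vals)),
            )
        )
    return out


def lsd_letters(groups, alpha: float = 0.05) -> list[str]:
    """Compact-letter display from least-significant-difference t-tests.

    ``groups`` is a list of :class:`GroupSummary` or (mean, sd, n)
    triples.  Pairwise t statistics use the pooled within-group
    variance sum((n_i-1) s_i^2) / sum(n_i-1) with df = sum(n_i-1); two
    groups share a letter iff their pairwise p >= alpha.  Letter
    characters follow input order (the first group gets 'a'); the
    induced same-letter partition is invariant to input order.
    """
    triples = [
        (g.mean, g.sd, g.count) if isinstance(g, GroupSummary) else tuple(g) for g in groups
    ]
    if len(triples) < 2:
        raise ValueError("need at least 2 groups")
    if any(n < 2 for _, _, n in triples):
        raise ValueError("every group needs n >= 2")
    means = np.array([t[0] for t in triples])
    sds = np.array([t[1] for t in triples])
    ns = np.array([t[2] for t in triples])
    df = int(np.sum(ns - 1))
    pooled = float(np.sum((ns - 1) * sds**2) / np.sum(ns - 1))
    k = len(triples)

    def significant(i, j):
        if pooled == 0:
            return means[i] != means[j]
        t = abs(means[i] - means[j]) / np.sqrt(pooled * (1 / ns[i] + 1 / ns[j]))
        return 2.0 * stats.t.sf(t, df) < alpha

    # Piepho insert-and-absorb over groups ordered by descending mean
    order = list(np.argsort(-means, kind="stable"))
    cols: list[set[int]] = [set(order)]
    for a_pos in range(k):
        for b_pos in range(a_pos + 1, k):
            i, j = order[a_pos], order[b_pos]
            if not significant(i, j):
                continue
            for c in [c for c in cols if i in c and j in c]:
                cols.remove(c)
                cols.extend([c - {i}, c - {j}])
            cols = [c for c in cols if c and not any(c < d for d in cols if d is not c)]
    # deduplicate and order columns by their best-ranked member
    uniq: list[set[int]] = []
    for c in cols:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(c))
    letters = ["" for _ in range(k)]
    for letter_idx, c in enumerate(uniq):
        ch = chr(ord("a") + letter_idx)
        for g in c:
            letters[g] += ch
    return ["".join(sorted(s)) for s in letters]
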