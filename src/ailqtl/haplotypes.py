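"""Haplotype-block detection and block/ancestry association.

Blocks are found with the D' confidence-interval rule: a marker pair is
in "strong LD" when the likelihood-based 90% CI on |D'| has lower bound
>= 0.70 and upper bound >= 0.98, shows "strong recombination" when the
upper bound is < 0.90, and a contiguous span is accepted as a block
when at least 95% of its informative pairs are strong.  The CI is
computed from unphased-equivalent two-locus genotype counts on a
likelihood grid over |D'|.

Association replaces the single-marker allele count with per-haplotype
dosage columns (0/1/2 copies of each non-reference haplotype) in the
same sex + generation fixed-effect model, tested jointly by F-test.
Ancestry association is the same model with donor-breed dosages from an
externally provided painting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, MarkerMap, SampleRecord
from .gwas import _covariate_matrix, _phenotype_vector


@dataclass
class HaplotypeBlock:
    chrom: str
    first: int  # index of first marker in the panel
    last: int
    marker_ids: list[str]


@dataclass
class HaplotypeAssignment:
    block: HaplotypeBlock | None
    sample_ids: list[str]
    labels: np.ndarray  # (n, 2) array of label strings
    frequencies: dict[str, float]
    n_excluded: int = 0


@dataclass
class HaplotypeAssociationResult:
    block: HaplotypeBlock | None
    frequencies: dict[str, float]
    effects: dict[str, float]
    effect_se: dict[str, float] = field(default_factory=dict)
    joint_f: float = float("nan")
    df_num: int = 0
    df_den: int = 0
    pvalue: float = float("nan")
    neglog10p: float = float("nan")
    n_used: int = 0
    reference: str = ""
    flag: str | None = None


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------


def pair_ld(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from phased haplotype alleles (flat 0/1 arrays)."""
    a = np.asarray(hap_a).ravel().astype(float)
    b = np.asarray(hap_b).ravel().astype(float)
    pa, pb = a.mean(), b.mean()
    d = float((a * b).mean() - pa * pb)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return d, 0.0, 0.0
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if d >= 0 else min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, float(dprime), float(r2)


def _genotype_table(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    keep = (ga != MISSING) & (gb != MISSING)
    tbl = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            tbl[i, j] = np.sum((ga[keep] == i) & (gb[keep] == j))
    return tbl


def _two_locus_probs(h: np.ndarray) -> np.ndarray:
    """Genotype-pair probabilities from haplotype freqs h[xA, xB] under random union."""
    p = np.zeros((3, 3))
    for x1 in range(2):
        for y1 in range(2):
            for x2 in range(2):
                for y2 in range(2):
                    p[x1 + x2, y1 + y2] += h[x1, y1] * h[x2, y2]
    return p


def dprime_ci(
    ga: np.ndarray, gb: np.ndarray, grid: int = 200, coverage: float = 0.90
) -> tuple[float, float]:
    """Likelihood-based CI on |D'| from unphased two-locus genotype counts.

    The likelihood of the 3x3 genotype table (double heterozygotes
    contribute both phase configurations) is evaluated on a grid of
    |D'| values at the MLE allele frequencies, for the better-supported
    sign of D; the central ``coverage`` interval of the normalized
    likelihood is returned.
    """
    tbl = _genotype_table(np.asarray(ga), np.asarray(gb))
    n = tbl.sum()
    if n == 0:
        return 0.0, 1.0
    pa = float((tbl * np.arange(3)[:, None]).sum() / (2 * n))
    pb = float((tbl * np.arange(3)[None, :]).sum() / (2 * n))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0, 1.0

    def loglik_grid(sign: int) -> np.ndarray:
        dmax = min(pa * (1 - pb), (1 - pa) * pb) if sign > 0 else min(pa * pb, (1 - pa) * (1 - pb))
        lls = np.empty(grid + 1)
        for k in range(grid + 1):
            d = sign * (k / grid) * dmax
            h = np.array(
                [
                    [(1 - pa) * (1 - pb) + d, (1 - pa) * pb - d],
                    [pa * (1 - pb) - d, pa * pb + d],
                ]
            )
            h = np.clip(h, 1e-12, None)
            probs = np.clip(_two_locus_probs(h), 1e-300, None)
            lls[k] = float(np.sum(tbl * np.log(probs)))
        return lls

    ll_pos, ll_neg = loglik_grid(+1), loglik_grid(-1)
    lls = ll_pos if ll_pos.max() >= ll_neg.max() else ll_neg
    w = np.exp(lls - lls.max())
    cdf = np.cumsum(w) / w.sum()
    tail = (1.0 - coverage) / 2.0
    lo = float(np.searchsorted(cdf, tail) / grid)
    hi = float(np.searchsorted(cdf, 1.0 - tail) / grid)
    return lo, min(hi, 1.0)


def classify_pair(
    ga: np.ndarray,
    gb: np.ndarray,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
) -> str:
    """'strong', 'recomb', or 'uninformative' by the CI rule."""
    lo, hi = dprime_ci(ga, gb)
    if lo >= ci_low and hi >= ci_high:
        return "strong"
    if hi < recomb_high:
        return "recomb"
    return "uninformative"


# ---------------------------------------------------------------------------
# Block finding
# ---------------------------------------------------------------------------


def find_blocks(
    genotypes: GenotypeMatrix,
    markers: MarkerMap,
    maf_min: float = 0.05,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
    frac_strong: float = 0.95,
    max_span: int = 50,
) -> list[HaplotypeBlock]:
    """Partition (a subset of) markers into non-overlapping LD blocks.

    Only markers with MAF >= ``maf_min`` are eligible.  Candidate spans
    of consecutive eligible markers (up to ``max_span`` long) are
    accepted greedily from longest to shortest (ties by position) when
    >= ``frac_strong`` of their informative pairs are in strong LD.
    Deterministic given the input.
    """
    calls = genotypes.calls
    elig = []
    for j in range(genotypes.n_markers):
        col = calls[:, j]
        nm = col[col != MISSING]
        if len(nm) == 0:
            continue
        aaf = nm.sum() / (2 * len(nm))
        if min(aaf, 1 - aaf) >= maf_min:
            elig.append(j)
    if len(elig) < 2:
        return []

    # classify pairs lazily with a cache
    cache: dict[tuple[int, int], str] = {}

    def cls(u: int, v: int) -> str:
        key = (u, v)
        if key not in cache:
            cache[key] = classify_pair(
                calls[:, elig[u]], calls[:, elig[v]], ci_low, ci_high, recomb_high
            )
        return cache[key]

    k = len(elig)
    candidates = []
    for span in range(min(k, max_span), 1, -1):
        for a in range(0, k - span + 1):
            candidates.append((a, a + span - 1))
    accepted: list[tuple[int, int]] = []
    taken = np.zeros(k, dtype=bool)
    for a, b in candidates:
        if taken[a : b + 1].any():
            continue
        # markers must also be consecutive in the full panel for contiguity
        if elig[b] - elig[a] != b - a:
            continue
        n_strong = n_inform = 0
        for u in range(a, b + 1):
            for v in range(u + 1, b + 1):
                c = cls(u, v)
                if c == "strong":
                    n_strong += 1
                    n_inform += 1
                elif c == "recomb":
                    n_inform += 1
        if n_inform == 0 or n_strong / n_inform < frac_strong:
            continue
        accepted.append((a, b))
        taken[a : b + 1] = True
    accepted.sort()
    blocks = []
    for a, b in accepted:
        idx = elig[a : b + 1]
        blocks.append(
            HaplotypeBlock(
                chrom=str(markers.chrom[idx[0]]),
                first=idx[0],
                last=idx[-1],
                marker_ids=[genotypes.marker_ids[j] for j in idx],
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Haplotype assignment and association
# ---------------------------------------------------------------------------


def assign_haplotypes(
    genotypes: GenotypeMatrix,
    block: HaplotypeBlock,
    pool_threshold: float = 0.01,
) -> HaplotypeAssignment:
    """Label each sample's two haplotypes over a block.

    Haplotype strings are ranked by frequency and labeled H1, H2, ...;
    haplotypes rarer than ``pool_threshold`` are pooled into OTHER.
    Samples with missing phase anywhere in the block are excluded and
    counted.
    """
    if genotypes.phase is None:
        raise ValueError("phased genotypes required for haplotype assignment")
    idx = [genotypes.marker_index(m) for m in block.marker_ids]
    haps = genotypes.haplotypes(idx)  # (n, 2, k)
    ok = (haps >= 0).all(axis=(1, 2))
    n_excluded = int((~ok).sum())
    haps = haps[ok]
    sample_ids = [s for s, o in zip(genotypes.sample_ids, ok) if o]
    strings = np.array(
        [["".join(map(str, haps[i, h])) for h in range(2)] for i in range(len(haps))],
        dtype=object,
    )
    uniq, counts = np.unique(strings.ravel(), return_counts=True)
    total = counts.sum()
    order = np.argsort(-counts, kind="stable")
    label_of: dict[str, str] = {}
    freqs: dict[str, float] = {}
    rank = 1
    for o in order:
        f = counts[o] / total
        if f < pool_threshold:
            label_of[uniq[o]] = "OTHER"
            freqs["OTHER"] = freqs.get("OTHER", 0.0) + f
        else:
            lab = f"H{rank}"
            label_of[uniq[o]] = lab
            freqs[lab] = float(f)
            rank += 1
    labels = np.vectorize(label_of.get)(strings)
    return HaplotypeAssignment(block, sample_ids, labels, freqs, n_excluded)


def _dosage_fit(
    y,
    samples: Sequence[SampleRecord],
    sample_ids: list[str],
    labels: np.ndarray,
    frequencies: dict[str, float],
    covariates: tuple[str, ...],
    block=None,
) -> HaplotypeAssociationResult:
    """Joint F-test of per-label dosage columns vs the covariate-only model."""
    by_id = {s.sample_id: (s, yi) for s, yi in zip(samples, _phenotype_vector(y, samples))}
    rows, sub, yy = [], [], []
    for sid, labpair in zip(sample_ids, labels):
        if sid not in by_id:
            continue
        s, yi = by_id[sid]
        if not np.isfinite(yi):
            continue
        rows.append(labpair)
        sub.append(s)
        yy.append(yi)
    n = len(sub)
    label_names = sorted(frequencies, key=lambda l: (-frequencies[l], l))
    if n == 0 or len(label_names) < 2:
        return HaplotypeAssociationResult(
            block, frequencies, {}, n_used=n, flag="fewer_than_2_labels"
        )
    reference = label_names[0]
    others = label_names[1:]
    dosage = np.zeros((n, len(others)))
    for i, labpair in enumerate(rows):
        for h in range(2):
            if labpair[h] in others:
                dosage[i, others.index(labpair[h])] += 1
    yy = np.asarray(yy)
    x0, _ = _covariate_matrix(sub, covariates)
    flag = None
    # drop dosage columns that are collinear within the full design
    keep = list(range(len(others)))
    while keep:
        x1 = np.column_stack([x0, dosage[:, keep]])
        if np.linalg.matrix_rank(x1) == x1.shape[1]:
            break
        keep.pop()  # pool the rarest label into the reference side
        flag = "collinear_labels_pooled"
    others_kept = [others[i] for i in keep]
    x1 = np.column_stack([x0, dosage[:, keep]]) if keep else x0
    q = len(keep)
    b0, rss0, _, _ = np.linalg.lstsq(x0, yy, rcond=None)
    rss0 = float(rss0[0]) if len(rss0) else float(np.sum((yy - x0 @ b0) ** 2))
    b1, rss1, rank1, _ = np.linalg.lstsq(x1, yy, rcond=None)
    rss1 = float(rss1[0]) if len(rss1) else float(np.sum((yy - x1 @ b1) ** 2))
    df_den = n - x1.shape[1]
    if q == 0 or df_den <= 0:
        return HaplotypeAssociationResult(
            block, frequencies, {}, n_used=n, reference=reference, flag="no_testable_labels"
        )
    effects = {lab: float(b1[x0.shape[1] + i]) for i, lab in enumerate(others_kept)}
    effects[reference] = 0.0
    se = {}
    if rss1 > 0:
        xtx_inv = np.linalg.inv(x1.T @ x1)
        sigma2 = rss1 / df_den
        for i, lab in enumerate(others_kept):
            j = x0.shape[1] + i
            se[lab] = float(np.sqrt(sigma2 * xtx_inv[j, j]))
        f = ((rss0 - rss1) / q) / sigma2
        p = float(stats.f.sf(f, q, df_den))
    else:
        f, p = float("inf"), 0.0
        flag = "degenerate"
    return HaplotypeAssociationResult(
        block,
        frequencies,
        effects,
        se,
        float(f),
        q,
        df_den,
        p,
        float(-np.log10(p)) if p > 0 else float("inf"),
        n,
        reference,
        flag,
    )


def fit_haplotype_lm(
    y,
    samples: Sequence[SampleRecord],
    assignment: HaplotypeAssignment,
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> HaplotypeAssociationResult:
    """OLS with haplotype-dosage columns replacing the marker effect."""
    return _dosage_fit(
        y,
        samples,
        assignment.sample_ids,
        assignment.labels,
        assignment.frequencies,
        covariates,
        block=assignment.block,
    )


def haplotype_scan(
    y,
    samples: Sequence[SampleRecord],
    genotypes: GenotypeMatrix,
    blocks: Sequence[HaplotypeBlock],
    pool_threshold: float = 0.01,
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> list[HaplotypeAssociationResult]:
    return [
        fit_haplotype_lm(y, samples, assign_haplotypes(genotypes, b, pool_threshold), covariates)
        for b in blocks
    ]


def ancestry_association(
    y,
    samples: Sequence[SampleRecord],
    labels: pd.DataFrame,
    segment: tuple[str, int, int],
    covariates: tuple[str, ...] = ("sex", "generation"),
) -> HaplotypeAssociationResult:
    """Donor-breed dosage association over one genomic segment.

    ``labels`` is the ancestry-painting table (sample_id, chrom, start,
    end, hap in {1,2}, donor); a sample enters only if both of its
    haplotypes carry a single donor label spanning the whole segment.
    With a single donor class the result is a flagged skip.
    """
    chrom, start, end = segment
    cover = labels[
        (labels["chrom"].astype(str) == str(chrom))
        & (labels["start"] <= start)
        & (labels["end"] >= end)
    ]
    donor_of: dict[tuple[str, int], str] = {}
    for _, r in cover.iterrows():
        donor_of[(str(r["sample_id"]), int(r["hap"]))] = str(r["donor"])
    sample_ids, pairs = [], []
    for s in samples:
        d1 = donor_of.get((s.sample_id, 1))
        d2 = donor_of.get((s.sample_id, 2))
        if d1 is None or d2 is None:
            continue
        sample_ids.append(s.sample_id)
        pairs.append([d1, d2])
    if not pairs:
        return HaplotypeAssociationResult(None, {}, {}, flag="no_labeled_samples")
    arr = np.array(pairs, dtype=object)
    uniq, counts = np.unique(arr.ravel(), return_counts=True)
    freqs = {str(u): float(c / counts.sum()) for u, c in zip(uniq, counts)}
    if len(freqs) < 2:
        return HaplotypeAssociationResult(None, freqs, {}, flag="single_donor_class")
    return _dosage_fit(y, samples, sample_ids, arr, freqs, covariates)
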