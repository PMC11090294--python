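"""Calibration, power and parameter-recovery studies on synthetic AILs.

These are the package's standard simulation studies: type-I-error
calibration of both scans under a null intercross, effect-recovery
Monte Carlos for the single-marker, NOIA and haplotype models, vQTL
detection power, the masking-epistasis stratification pattern, and the
ancestral-haplotype contrast.  Each takes a seed and returns plain
numbers, so they can be driven from tests or scripts.

Problem sizes are the package's defaults: calibration on the full
2,000-marker / ~3,000-bird panel; the power and epistasis studies on a
500-marker 100-cM panel (0.2 cM spacing) at the same cohort size.
"""

from __future__ import annotations

import numpy as np

from .gwas import fit_marker_lm, gwas_scan, normalize_by_group
from .haplotypes import HaplotypeBlock, assign_haplotypes, fit_haplotype_lm
from .io import GenotypeMatrix, SampleRecord
from .noia import LocusFrequencies, conditional_scan, fit_noia, single_locus_design
from .sim import SimConfig, TraitArchitecture, simulate
from .vgwas import vgwas_scan


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _simple_samples(n: int, rng: np.random.Generator, bw8=None) -> list[SampleRecord]:
    sexes = rng.random(n) < 0.5
    gens = rng.integers(2, 5, n)
    return [
        SampleRecord(
            f"s{i}",
            "M" if sexes[i] else "F",
            int(gens[i]),
            bw8=None if bw8 is None else float(bw8[i]),
        )
        for i in range(n)
    ]


def null_calibration(seed: int, n_reps: int = 40, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the GWAS t-test and Brown-Forsythe scan.

    Runs ``n_reps`` independent null AIL simulations at the default
    scale (2,000 markers, ~3,000 phenotyped birds; sex and generation
    effects present, no genetic effects) and pools the fraction of
    markers with p < alpha across replicates.
    """
    g_hits = g_tot = v_hits = v_tot = 0
    for s in _child_seeds(seed, n_reps):
        res = simulate(SimConfig(seed=s))
        ph = [x for x in res.samples if x.bw8 is not None]
        y = np.array([x.bw8 for x in ph])
        yn = normalize_by_group(ph)
        for r in gwas_scan(y, ph, res.genotypes):
            if r.flag is None:
                g_hits += r.pvalue < alpha
                g_tot += 1
        for r in vgwas_scan(yn, ph, res.genotypes):
            if r.flag is None:
                v_hits += r.pvalue < alpha
                v_tot += 1
    return {
        "gwas_rate": g_hits / g_tot,
        "vgwas_rate": v_hits / v_tot,
        "n_markers": g_tot // n_reps,
        "n_reps": n_reps,
    }


def additive_recovery(seed: int, reps: int = 500, n: int = 800, effect: float = 10.0) -> float:
    """Fraction of replicates with the additive estimate within +/- 2 se."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.4, n).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(n)], ["mk"], g[:, None])
        samples = _simple_samples(n, rng)
        sex = np.array([s.sex == "M" for s in samples])
        gen = np.array([s.generation for s in samples])
        y = effect * g + 120.0 * sex + 5.0 * gen + rng.normal(0, 150.0, n)
        r = fit_marker_lm(y, samples, gm, "mk")
        hits += abs(r.effect - effect) <= 2 * r.se
    return hits / reps


def noia_recovery(
    seed: int, reps: int = 300, n: int = 3000, a: float = 5.0, d: float = 2.0, aa: float = 4.0
) -> dict:
    """Per-effect coverage of +/- 2 se intervals for NOIA a, d and aa."""
    rng = np.random.default_rng(seed)
    hits = {"a": 0, "d": 0, "aa": 0}
    for _ in range(reps):
        ga = rng.binomial(2, 0.4, n).astype(np.int8)
        gb = rng.binomial(2, 0.6, n).astype(np.int8)
        da = single_locus_design(LocusFrequencies.from_genotypes(ga))
        db = single_locus_design(LocusFrequencies.from_genotypes(gb))
        y = (
            a * da.rows[ga, 1]
            + d * da.rows[ga, 2]
            + aa * da.rows[ga, 1] * db.rows[gb, 1]
            + rng.normal(size=n)
        )
        gm = GenotypeMatrix([f"s{i}" for i in range(n)], ["A", "B"], np.column_stack([ga, gb]))
        fit = fit_noia(y, gm, ["A", "B"])
        hits["a"] += abs(fit.effects["a_A"] - a) <= 2 * fit.se["a_A"]
        hits["d"] += abs(fit.effects["d_A"] - d) <= 2 * fit.se["d_A"]
        hits["aa"] += abs(fit.effects["aa_A:B"] - aa) <= 2 * fit.se["aa_A:B"]
    return {k: v / reps for k, v in hits.items()}


def haplotype_recovery(seed: int, reps: int = 400, n: int = 600, effect: float = 20.0) -> float:
    """Coverage of +/- 2 se for a block-haplotype effect estimate."""
    rng = np.random.default_rng(seed)
    pool = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
    hits = 0
    for _ in range(reps):
        draws = rng.choice(3, size=(n, 2), p=[0.5, 0.3, 0.2])
        haps = pool[draws]  # (n, 2, m)
        phase = haps.transpose(0, 2, 1)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], ["m0", "m1"], phase.sum(axis=2), phase
        )
        carrier = (draws == 2).sum(axis=1)
        samples = _simple_samples(n, rng)
        sex = np.array([s.sex == "M" for s in samples])
        y = effect * carrier + 50.0 * sex + rng.normal(0, 30.0, n)
        asn = assign_haplotypes(gm, HaplotypeBlock("1", 0, 1, ["m0", "m1"]))
        res = fit_haplotype_lm(y, samples, asn)
        if "H3" not in res.effects or "H3" not in res.effect_se:
            continue
        hits += abs(res.effects["H3"] - effect) <= 2 * res.effect_se["H3"]
    return hits / reps


def _power_config(seed: int, arch: TraitArchitecture) -> SimConfig:
    return SimConfig(seed=seed, n_markers=500, architecture=arch)


VQTL_MARKER = "m00250"


def vqtl_power(seed: int, reps: int = 200, multipliers=(1.0, 1.0, 2.0)) -> float:
    """Power of the Brown-Forsythe scan to rank a simulated vQTL top of panel."""
    wins = 0
    for s in _child_seeds(seed, reps):
        arch = TraitArchitecture(vqtl={VQTL_MARKER: tuple(multipliers)})
        res = simulate(_power_config(s, arch))
        ph = [x for x in res.samples if x.bw8 is not None]
        yn = normalize_by_group(ph)
        scan = vgwas_scan(yn, ph, res.genotypes)
        top = max((r for r in scan if r.flag is None), key=lambda r: r.f_bf)
        wins += top.marker_id == VQTL_MARKER
    return wins / reps


MASK_HUB = "m00125"
MASK_FOCAL = "m00375"


def masking_epistasis(seed: int, effect_per_allele: float = -40.0) -> dict:
    """Stratified scan under masking epistasis.

    The focal locus shifts weight by ``effect_per_allele`` per ALT
    allele only when the hub carries at least one REF allele; in hub
    ALT homozygotes the focal locus is silent.  Returns the focal
    marker's -log10 p within each hub-genotype stratum.
    """
    grid = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            grid[i, j] = effect_per_allele * i if j < 2 else 0.0
    arch = TraitArchitecture(epistatic_pairs={(MASK_FOCAL, MASK_HUB): grid})
    res = simulate(_power_config(seed, arch))
    ph = [x for x in res.samples if x.bw8 is not None]
    yn = normalize_by_group(ph)
    gsub = res.genotypes.subset_samples([s.sample_id for s in ph])
    cs = conditional_scan(yn, ph, gsub, MASK_HUB, scan_markers=[MASK_FOCAL])
    return {g: scan[0].neglog10p for g, scan in cs.strata.items()}


def ancestry_contrast(seed: int, n: int = 2000, effects=(26.0, -3.0)) -> dict:
    """Recover the contrast between two ancestral-haplotype effects.

    Simulates donor-labeled haplotypes worth ``effects`` grams against
    a zero-effect background donor and estimates the between-donor
    contrast with the donor-dosage model.
    """
    import pandas as pd

    from .haplotypes import ancestry_association

    rng = np.random.default_rng(seed)
    donors = rng.choice(["A", "B", "C"], p=[0.25, 0.25, 0.5], size=(n, 2))
    value = {"A": effects[0], "B": effects[1], "C": 0.0}
    samples = _simple_samples(n, rng)
    sex = np.array([s.sex == "M" for s in samples])
    y = (
        np.vectorize(value.get)(donors).sum(axis=1)
        + 120.0 * sex
        + rng.normal(0, 60.0, n)
    )
    rows = []
    for i in range(n):
        for hap in (1, 2):
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "chrom": "1",
                    "start": 1,
                    "end": 10_000,
                    "hap": hap,
                    "donor": donors[i, hap - 1],
                }
            )
    res = ancestry_association(y, samples, pd.DataFrame(rows), ("1", 100, 5000))
    return {
        "contrast": res.effects["A"] - res.effects["B"],
        "pvalue": res.pvalue,
        "n_used": res.n_used,
    }
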