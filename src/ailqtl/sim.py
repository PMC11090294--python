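"""Synthetic advanced-intercross-line (AIL) generator.

Emulates the statistical structure of a bidirectional-selection cross:
two divergent founder lines (HIGH/LOW), an F1 cross between them, and
multigenerational random intercrossing (F2 onward) that accumulates
recombination.  Meiosis follows Haldane's map function (inter-marker
crossovers are independent Bernoulli events with probability
(1 - exp(-2d))/2 for map distance d Morgans; no interference).

The trait model is additive + dominance + explicit 3x3 epistatic grids
+ variance-heterogeneity (vQTL) loci that scale the residual standard
deviation per genotype, with sex and generation fixed effects — the
effect classes the downstream scans are designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    SampleRecord,
    write_phenotypes,
    write_vcf,
)


@dataclass
class TraitArchitecture:
    """Ground-truth genetic architecture of the simulated trait.

    Units are grams.  ``additive`` maps marker id to the effect of one
    ALT allele; ``dominance`` to the heterozygote deviation;
    ``epistatic_pairs`` maps a marker pair to a 3x3 genotype-value grid
    (rows = first marker's ALT count); ``vqtl`` maps a marker to
    residual-SD multipliers for genotypes 0/1/2.
    """

    intercept: float = 900.0
    sex_effect: float = 120.0
    generation_effects: Mapping[int, float] = field(default_factory=dict)
    additive: Mapping[str, float] = field(default_factory=dict)
    dominance: Mapping[str, float] = field(default_factory=dict)
    epistatic_pairs: Mapping[tuple[str, str], np.ndarray] = field(default_factory=dict)
    vqtl: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    residual_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for pair, grid in self.epistatic_pairs.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != (3, 3):
                raise ValueError(f"epistatic grid for {pair} is not 3x3")
        for m, mult in self.vqtl.items():
            if len(mult) != 3 or any(x <= 0 for x in mult):
                raise ValueError(f"vqtl multipliers for {m} must be 3 positive values")

    def marker_ids(self) -> set[str]:
        ids = set(self.additive) | set(self.dominance) | set(self.vqtl)
        for a, b in self.epistatic_pairs:
            ids |= {a, b}
        return ids


@dataclass
class SimConfig:
    """Full specification of the synthetic AIL pedigree and trait.

    Defaults emulate the study design scale: 2 x 20 founders, an F1 of
    80, intercross generations F2-F18 of 176 each (~3,000 phenotyped
    individuals), and 2,000 markers evenly spaced on one 100-cM
    chromosome with strongly divergent founder allele frequencies
    (0.9 vs 0.1).
    """

    seed: int = 0
    n_founders_per_line: int = 20
    n_f1: int = 80
    n_per_generation: Mapping[int, int] = field(
        default_factory=lambda: {g: 176 for g in range(2, 19)}
    )
    n_markers: int = 2000
    map_positions: np.ndarray | None = None  # centimorgans, increasing
    founder_freq_high: np.ndarray | float = 0.9
    founder_freq_low: np.ndarray | float = 0.1
    chrom: str = "1"
    architecture: TraitArchitecture = field(default_factory=TraitArchitecture)

    def __post_init__(self) -> None:
        if self.n_founders_per_line <= 0 or self.n_f1 <= 0 or self.n_markers <= 0:
            raise ValueError("all counts must be positive")
        if any(n <= 0 for n in self.n_per_generation.values()):
            raise ValueError("generation sizes must be positive")
        if sorted(self.n_per_generation) != list(
            range(min(self.n_per_generation), max(self.n_per_generation) + 1)
        ) or min(self.n_per_generation, default=2) < 2:
            raise ValueError("generations must be a contiguous range starting at >= 2")
        if self.map_positions is None:
            self.map_positions = np.linspace(0.0, 100.0, self.n_markers)
        self.map_positions = np.asarray(self.map_positions, dtype=float)
        if len(self.map_positions) != self.n_markers:
            raise ValueError("map_positions length != n_markers")
        if np.any(np.diff(self.map_positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        self.founder_freq_high = self._freq_array(self.founder_freq_high)
        self.founder_freq_low = self._freq_array(self.founder_freq_low)

    def _freq_array(self, f) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(f, dtype=float), (self.n_markers,)).copy()
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("founder frequencies must be in [0, 1]")
        return arr

    def marker_ids(self) -> list[str]:
        return [f"m{j:05d}" for j in range(self.n_markers)]

    def marker_map(self) -> MarkerMap:
        # physical coordinates: 15 kb per marker starting at 150 Mb, echoing
        # a ~30 Mb region; purely cosmetic for exports
        pos = 150_000_000 + np.arange(self.n_markers, dtype=np.int64) * 15_000 + 1
        n = self.n_markers
        return MarkerMap(
            np.array(self.marker_ids(), dtype=object),
            np.array([self.chrom] * n, dtype=object),
            pos,
            np.array(["A"] * n, dtype=object),
            np.array(["G"] * n, dtype=object),
        )


@dataclass
class PedigreeRecord:
    sample_id: str
    sire_id: str | None
    dam_id: str | None
    generation: int


@dataclass
class SimResult:
    genotypes: GenotypeMatrix  # phased, all generations
    samples: list[SampleRecord]
    pedigree: list[PedigreeRecord]
    markers: MarkerMap
    config: SimConfig


def default_generation_effects(generations: Sequence[int], slope: float = -2.0) -> dict[int, float]:
    """Small linear trend so the generation covariate is non-degenerate."""
    return {g: slope * (g - min(generations)) for g in generations}


# ---------------------------------------------------------------------------
# Founders and meiosis
# ---------------------------------------------------------------------------


def simulate_founders(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[SampleRecord]]:
    """Draw phased founder genotypes from each line's allele frequencies.

    Each haplotype allele is an independent Bernoulli draw from the
    line's per-marker ALT frequency; sexes are balanced within lines.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids, records, hap_blocks = [], [], []
    for line, freq in (("HIGH", cfg.founder_freq_high), ("LOW", cfg.founder_freq_low)):
        n = cfg.n_founders_per_line
        hap = (rng.random((n, cfg.n_markers, 2)) < freq[None, :, None]).astype(np.int8)
        hap_blocks.append(hap)
        for i in range(n):
            sid = f"{line}_{i:03d}"
            ids.append(sid)
            records.append(
                SampleRecord(sid, "M" if i % 2 == 0 else "F", 0, line=line)
            )
    phase = np.concatenate(hap_blocks, axis=0)
    gm = GenotypeMatrix(ids, cfg.marker_ids(), phase.sum(axis=2), phase)
    return gm, records


def meiosis(
    parent_phase: np.ndarray, map_positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a phased parent under Haldane's map function.

    ``parent_phase`` is (2, n_markers).  Crossovers between adjacent
    markers occur independently with probability (1 - exp(-2d))/2 for
    inter-marker distance d in Morgans; the gamete alternates source
    haplotype at each crossover, starting from a random haplotype.
    """
    return _gametes(parent_phase[None, :, :], map_positions, rng)[0]


def _recomb_fractions(map_positions: np.ndarray) -> np.ndarray:
    d_morgans = np.diff(map_positions) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def _gametes(
    phases: np.ndarray, map_positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized meiosis: phases (k, 2, m) -> gametes (k, m)."""
    k, _, m = phases.shape
    r = _recomb_fractions(map_positions)
    switch = rng.random((k, m - 1)) < r
    start = rng.integers(0, 2, size=(k, 1))
    source = (start + np.concatenate(
        [np.zeros((k, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1
    )) % 2
    return np.take_along_axis(phases, source[:, None, :], axis=1)[:, 0, :]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(
    cfg: SimConfig,
    founders: tuple[GenotypeMatrix, list[SampleRecord]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, list[SampleRecord], list[PedigreeRecord]]:
    """Simulate the full multigenerational intercross.

    F1 individuals take one HIGH and one LOW parent of opposite sexes;
    later generations mate random non-full-sib pairs from the previous
    generation.  Offspring genotypes are Mendelian by construction
    (each child receives one recombinant gamete per parent).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if founders is None:
        founders = simulate_founders(cfg, rng)
    f_gm, f_records = founders

    all_phase = [f_gm.phase]
    all_ids = list(f_gm.sample_ids)
    samples = list(f_records)
    pedigree = [PedigreeRecord(r.sample_id, None, None, 0) for r in f_records]

    by_line_sex: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(f_records):
        by_line_sex.setdefault((r.line, r.sex), []).append(i)

    def _new_generation(n_children, sire_pool, dam_pool, parent_of, gen, line, prefix):
        """sire_pool/dam_pool: global indices of eligible sires/dams."""
        if len(sire_pool) < 1 or len(dam_pool) < 1:
            raise ValueError(f"generation {gen}: fewer than 2 available parents")
        sires = rng.choice(sire_pool, size=n_children)
        dams = rng.choice(dam_pool, size=n_children)
        if parent_of is not None:  # avoid full-sib matings
            for t in range(n_children):
                tries = 0
                while parent_of[sires[t]] == parent_of[dams[t]] and tries < 100:
                    sires[t] = rng.choice(sire_pool)
                    dams[t] = rng.choice(dam_pool)
                    tries += 1
        phase_all = np.concatenate(all_phase, axis=0)
        pat = _gametes(phase_all[sires].transpose(0, 2, 1), cfg.map_positions, rng)
        mat = _gametes(phase_all[dams].transpose(0, 2, 1), cfg.map_positions, rng)
        child_phase = np.stack([pat, mat], axis=2)
        sexes = rng.random(n_children) < 0.5
        ids, recs, peds = [], [], []
        for t in range(n_children):
            sid = f"{prefix}_{t:04d}"
            ids.append(sid)
            recs.append(SampleRecord(sid, "M" if sexes[t] else "F", gen, line=line))
            peds.append(PedigreeRecord(sid, all_ids[sires[t]], all_ids[dams[t]], gen))
        return child_phase, ids, recs, peds

    # F1: HIGH x LOW
    sire_pool = by_line_sex.get(("HIGH", "M"), []) + by_line_sex.get(("LOW", "M"), [])
    dam_pool = by_line_sex.get(("LOW", "F"), []) + by_line_sex.get(("HIGH", "F"), [])
    # enforce cross-line pairs: pair each child with a HIGH sire + LOW dam or
    # LOW sire + HIGH dam, at random
    n_f1 = cfg.n_f1
    hm, lm = by_line_sex.get(("HIGH", "M"), []), by_line_sex.get(("LOW", "M"), [])
    hf, lf = by_line_sex.get(("HIGH", "F"), []), by_line_sex.get(("LOW", "F"), [])
    if not ((hm and lf) or (lm and hf)):
        raise ValueError("cannot form HIGH x LOW pairs from the founders")
    f1_phase = np.empty((n_f1, cfg.n_markers, 2), dtype=np.int8)
    f1_ids, f1_recs, f1_peds = [], [], []
    phase_all = np.concatenate(all_phase, axis=0)
    sire_idx = np.empty(n_f1, dtype=int)
    dam_idx = np.empty(n_f1, dtype=int)
    for t in range(n_f1):
        if (hm and lf) and (not (lm and hf) or rng.random() < 0.5):
            sire_idx[t], dam_idx[t] = rng.choice(hm), rng.choice(lf)
        else:
            sire_idx[t], dam_idx[t] = rng.choice(lm), rng.choice(hf)
    pat = _gametes(phase_all[sire_idx].transpose(0, 2, 1), cfg.map_positions, rng)
    mat = _gametes(phase_all[dam_idx].transpose(0, 2, 1), cfg.map_positions, rng)
    f1_phase = np.stack([pat, mat], axis=2)
    f1_sex = rng.random(n_f1) < 0.5
    for t in range(n_f1):
        sid = f"F01_{t:04d}"
        f1_ids.append(sid)
        f1_recs.append(SampleRecord(sid, "M" if f1_sex[t] else "F", 1, line="CROSS"))
        f1_peds.append(PedigreeRecord(sid, all_ids[sire_idx[t]], all_ids[dam_idx[t]], 1))
    all_phase.append(f1_phase)
    all_ids += f1_ids
    samples += f1_recs
    pedigree += f1_peds
    prev_range = range(len(all_ids) - n_f1, len(all_ids))

    parent_of = {}
    for i in prev_range:
        parent_of[i] = (pedigree[i].sire_id, pedigree[i].dam_id)

    for gen in sorted(cfg.n_per_generation):
        n_children = cfg.n_per_generation[gen]
        sire_pool = [i for i in prev_range if samples[i].sex == "M"]
        dam_pool = [i for i in prev_range if samples[i].sex == "F"]
        child_phase, ids, recs, peds = _new_generation(
            n_children, sire_pool, dam_pool, parent_of, gen, "CROSS", f"F{gen:02d}"
        )
        all_phase.append(child_phase)
        start = len(all_ids)
        all_ids += ids
        samples += recs
        pedigree += peds
        prev_range = range(start, len(all_ids))
        parent_of = {i: (pedigree[i].sire_id, pedigree[i].dam_id) for i in prev_range}

    phase = np.concatenate(all_phase, axis=0)
    gm = GenotypeMatrix(all_ids, cfg.marker_ids(), phase.sum(axis=2), phase)
    return gm, samples, pedigree


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    samples: Sequence[SampleRecord],
    arch: TraitArchitecture,
    seed: int | np.random.Generator = 0,
    phenotyped_generations: Sequence[int] | None = None,
) -> list[SampleRecord]:
    """Assign BW8 phenotypes under the configured trait architecture.

    bw8 = intercept + sex_effect*1[M] + generation effect
          + sum additive*count + sum dominance*1[het] + grid lookups
          + eps,  eps ~ N(0, residual_sd * prod vqtl multipliers).

    By default only intercross generations (>= 2) are phenotyped,
    matching a design where founders and F1 are not measured.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing_markers = arch.marker_ids() - set(genotypes.marker_ids)
    if missing_markers:
        raise ValueError(f"architecture markers absent from panel: {sorted(missing_markers)}")

    idx = [genotypes.sample_index(s.sample_id) for s in samples]
    n = len(samples)
    mu = np.full(n, arch.intercept, dtype=float)
    sexes = np.array([s.sex == "M" for s in samples])
    mu += arch.sex_effect * sexes
    mu += np.array([arch.generation_effects.get(s.generation, 0.0) for s in samples])

    def geno(marker):
        col = genotypes.column(marker)[idx]
        if np.any(col == MISSING):
            raise ValueError(f"missing genotype at architecture marker {marker}")
        return col

    for m, a in arch.additive.items():
        mu += a * geno(m)
    for m, d in arch.dominance.items():
        mu += d * (geno(m) == 1)
    for (ma, mb), grid in arch.epistatic_pairs.items():
        grid = np.asarray(grid, dtype=float)
        mu += grid[geno(ma), geno(mb)]
    sd = np.full(n, arch.residual_sd, dtype=float)
    for m, mult in arch.vqtl.items():
        sd *= np.asarray(mult, dtype=float)[geno(m)]
    bw8 = mu + rng.normal(0.0, 1.0, size=n) * sd

    gens = set(phenotyped_generations) if phenotyped_generations is not None else None
    out = []
    for s, w in zip(samples, bw8):
        measured = (s.generation >= 2) if gens is None else (s.generation in gens)
        out.append(
            SampleRecord(s.sample_id, s.sex, s.generation, s.line, float(w) if measured else None)
        )
    return out


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: founders -> pedigree -> phenotypes."""
    rng = np.random.default_rng(cfg.seed)
    gm, samples, pedigree = simulate_pedigree(cfg, rng=rng)
    samples = simulate_phenotypes(gm, samples, cfg.architecture, rng)
    return SimResult(gm, samples, pedigree, cfg.marker_map(), cfg)


# ---------------------------------------------------------------------------
# Export / config files
# ---------------------------------------------------------------------------


def export(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, phenotype, pedigree and ground-truth architecture files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "architecture": outdir / "architecture.tsv",
    }
    write_vcf(paths["vcf"], result.genotypes, result.markers)
    write_phenotypes(paths["phenotypes"], result.samples)
    with open(paths["pedigree"], "w") as fh:
        fh.write("sample_id\tsire_id\tdam_id\tgeneration\n")
        for p in result.pedigree:
            fh.write(f"{p.sample_id}\t{p.sire_id or 'NA'}\t{p.dam_id or 'NA'}\t{p.generation}\n")
    arch = result.config.architecture
    with open(paths["architecture"], "w") as fh:
        fh.write("component\tmarkers\tvalue\n")
        fh.write(f"intercept\t.\t{arch.intercept}\n")
        fh.write(f"sex_effect\t.\t{arch.sex_effect}\n")
        fh.write(f"residual_sd\t.\t{arch.residual_sd}\n")
        for g, e in sorted(arch.generation_effects.items()):
            fh.write(f"generation_effect\t{g}\t{e}\n")
        for m, a in arch.additive.items():
            fh.write(f"additive\t{m}\t{a}\n")
        for m, d in arch.dominance.items():
            fh.write(f"dominance\t{m}\t{d}\n")
        for (ma, mb), grid in arch.epistatic_pairs.items():
            fh.write(f"epistatic_grid\t{ma},{mb}\t{json.dumps(np.asarray(grid).tolist())}\n")
        for m, mult in arch.vqtl.items():
            fh.write(f"vqtl\t{m}\t{json.dumps(list(mult))}\n")
    return paths


def config_from_yaml(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    arch_raw = raw.pop("architecture", {})
    pairs = {
        tuple(k.split(",")): np.asarray(v, dtype=float)
        for k, v in (arch_raw.pop("epistatic_pairs", {}) or {}).items()
    }
    vqtl = {k: tuple(v) for k, v in (arch_raw.pop("vqtl", {}) or {}).items()}
    gen_eff = {int(k): float(v) for k, v in (arch_raw.pop("generation_effects", {}) or {}).items()}
    arch = TraitArchitecture(
        generation_effects=gen_eff, epistatic_pairs=pairs, vqtl=vqtl, **arch_raw
    )
    if "n_per_generation" in raw:
        raw["n_per_generation"] = {int(k): int(v) for k, v in raw["n_per_generation"].items()}
    return SimConfig(architecture=arch, **raw)
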