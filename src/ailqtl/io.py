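"""Data model and readers/writers for the formats the pipeline touches.

Genotypes are coded as counts of the VCF ALT allele (0, 1, 2) with
``MISSING = -1`` for uncalled genotypes.  Coordinates are 1-based and
inclusive throughout, matching VCF.  Only biallelic SNPs enter the
analysis; indels and multi-allelic records are skipped and counted.
REF/ALT orientation is taken from the VCF and never re-polarized by
frequency.  Missing calls propagate; there is no internal imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING: int = -1

SEX_CODES = ("F", "M")
LINE_CODES = ("HIGH", "LOW", "CROSS", "NA")


@dataclass
class SampleRecord:
    """One phenotyped (or founder) individual.

    ``generation`` is 0 for founders, 1 for the F1 cross and 2..k for
    intercross generations.  ``bw8`` is body weight at eight weeks in
    grams; ``None`` when not measured.
    """

    sample_id: str
    sex: str
    generation: int
    line: str = "NA"
    bw8: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValueError(f"unknown sex code {self.sex!r} for {self.sample_id}")
        if self.line not in LINE_CODES:
            raise ValueError(f"unknown line code {self.line!r} for {self.sample_id}")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")


@dataclass
class MarkerMap:
    """Marker coordinates: id, chromosome, 1-based position, REF and ALT."""

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n = len(self.marker_id)
        for name in ("chrom", "pos", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError("MarkerMap fields have inconsistent lengths")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ValueError("ref == alt for some marker")

    def __len__(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


@dataclass
class AnnotatedVariant:
    """Functional annotation attached to one marker (snpEff-style ANN)."""

    marker_id: str
    effect_category: str = ""
    gene_name: str = ""
    transcript_change: str = ""
    protein_change: str = ""
    phylop: float = float("nan")
    aaf: float = float("nan")


class GenotypeMatrix:
    """Samples x markers matrix of ALT-allele counts, optionally phased.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered identifiers for rows and columns.
    calls
        ``(n_samples, n_markers)`` integer array with values in
        {0, 1, 2, MISSING}.
    phase
        Optional ``(n_samples, n_markers, 2)`` array of per-haplotype ALT
        indicators (0/1, MISSING for unphased cells).  Where present the
        two haplotype alleles must sum to the unphased call.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        calls: np.ndarray,
        phase: np.ndarray | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("calls shape inconsistent with id lists")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls outside {0,1,2,MISSING}")
        self.calls = calls
        if phase is not None:
            phase = np.asarray(phase, dtype=np.int8)
            if phase.shape != calls.shape + (2,):
                raise ValueError("phase shape must be calls shape + (2,)")
            known = (phase >= 0).all(axis=2) & (calls != MISSING)
            if not np.array_equal(phase[known].sum(axis=1), calls[known]):
                raise ValueError("phased alleles do not sum to unphased call")
        self.phase = phase
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}
        if len(self._sample_index) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self._marker_index) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        """ALT-allele counts for one marker, in sample order."""
        return self.calls[:, self.marker_index(marker_id)]

    def haplotypes(self, marker_idx: Sequence[int]) -> np.ndarray:
        """``(n_samples, 2, k)`` phased alleles at the given marker indices."""
        if self.phase is None:
            raise ValueError("genotypes are unphased")
        return np.transpose(self.phase[:, list(marker_idx), :], (0, 2, 1))

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        phase = self.phase[idx] if self.phase is not None else None
        return GenotypeMatrix(list(sample_ids), self.marker_ids, self.calls[idx], phase)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_ANN_FIELDS = 16  # snpEff ANN sub-field count


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, np.iinfo(np.int64).max
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_vcf(
    path: str | Path, region: str | None = None
) -> tuple[GenotypeMatrix, MarkerMap, list[AnnotatedVariant]]:
    """Read a VCF into a genotype matrix, marker map, and annotations.

    Only biallelic SNP records are kept; skipped records are counted and
    logged.  Genotypes are ALT-allele counts, ``./.`` becomes MISSING.
    Phase is retained when every genotype in the file is phased.  snpEff
    ``ANN`` entries (first transcript) populate the annotation list when
    present; an optional ``PHYLOP`` INFO field is carried through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    want = _parse_region(region) if region else None

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise ValueError("VCF contains no samples")
        rows: list[list[int]] = []
        hap_rows: list[np.ndarray] = []
        mid, chroms, poss, refs, alts = [], [], [], [], []
        annotations: list[AnnotatedVariant] = []
        n_skipped = 0
        all_phased = True
        for rec in vf:
            if want is not None:
                c, lo, hi = want
                if rec.chrom != c or not (lo <= rec.pos <= hi):
                    continue
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.alts[0] not in "ACGT"
                or rec.ref not in "ACGT"
            ):
                n_skipped += 1
                continue
            calls = np.full(len(samples), MISSING, dtype=np.int8)
            hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                sv = rec.samples[s]
                gt = sv["GT"]
                if gt is None or any(a is None for a in gt):
                    all_phased = False
                    continue
                calls[i] = sum(gt)
                if sv.phased and len(gt) == 2:
                    hap[i] = gt
                else:
                    all_phased = False
            marker = rec.id or f"{rec.chrom}_{rec.pos}"
            rows.append(calls)
            hap_rows.append(hap)
            mid.append(marker)
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            annotations.append(_annotation_from_record(rec, marker, calls))
        if n_skipped:
            logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError("no usable biallelic SNP records in VCF")
    calls = np.stack(rows, axis=1)
    phase = np.stack(hap_rows, axis=1) if all_phased else None
    gm = GenotypeMatrix(samples, mid, calls, phase)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    mm = MarkerMap(np.array(mid, dtype=object), chroms, poss, refs, alts)
    return gm, mm, annotations


def _annotation_from_record(rec, marker: str, calls: np.ndarray) -> AnnotatedVariant:
    nonmiss = calls[calls != MISSING]
    aaf = float(nonmiss.sum() / (2 * len(nonmiss))) if len(nonmiss) else float("nan")
    ann = AnnotatedVariant(marker_id=marker, aaf=aaf)
    info = rec.info
    if "PHYLOP" in info:
        v = info["PHYLOP"]
        ann.phylop = float(v[0] if isinstance(v, tuple) else v)
    if "ANN" in info:
        first = info["ANN"]
        if isinstance(first, tuple):
            first = first[0]
        parts = (first.split("|") + [""] * _ANN_FIELDS)[:_ANN_FIELDS]
        ann.effect_category = parts[1]
        ann.gene_name = parts[3]
        ann.transcript_change = parts[9]
        ann.protein_change = parts[10]
    return ann


def write_vcf(
    path: str | Path,
    genotypes: GenotypeMatrix,
    markers: MarkerMap,
) -> None:
    """Write an (optionally phased) VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in pd.unique(markers.chrom):
        length = int(markers.pos[markers.chrom == c].max()) + 1000
        header.add_line(f"##contig=<ID={c},length={length}>")
    for s in genotypes.sample_ids:
        header.add_sample(s)
    phased = genotypes.phase is not None
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, marker in enumerate(genotypes.marker_ids):
            rec = out.new_record(
                contig=str(markers.chrom[j]),
                start=int(markers.pos[j]) - 1,
                stop=int(markers.pos[j]),
                alleles=(str(markers.ref[j]), str(markers.alt[j])),
                id=str(marker),
            )
            for i, s in enumerate(genotypes.sample_ids):
                call = genotypes.calls[i, j]
                if call == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif phased:
                    rec.samples[s]["GT"] = tuple(int(a) for a in genotypes.phase[i, j])
                    rec.samples[s].phased = True
                else:
                    rec.samples[s]["GT"] = (0, 0) if call == 0 else ((0, 1) if call == 1 else (1, 1))
            out.write(rec)


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ("sample_id", "sex", "generation", "bw8")


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated phenotype table.

    Required columns: sample_id, sex, generation, bw8; optional: line.
    Unparseable bw8 values become missing; duplicate sample ids and
    unknown sex codes are fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns {sorted(missing_cols)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in phenotype table")
    bad_sex = ~df["sex"].isin(SEX_CODES)
    if bad_sex.any():
        raise ValueError(f"unknown sex code {df['sex'][bad_sex].iloc[0]!r}")
    bw8 = pd.to_numeric(df["bw8"], errors="coerce")
    lines = df["line"] if "line" in df.columns else pd.Series(["NA"] * len(df))
    return [
        SampleRecord(
            sample_id=r.sample_id,
            sex=r.sex,
            generation=int(r.generation),
            line=str(line) if str(line) in LINE_CODES else "NA",
            bw8=None if pd.isna(w) else float(w),
        )
        for (_, r), w, line in zip(df.iterrows(), bw8, lines)
    ]


def write_phenotypes(path: str | Path, samples: Iterable[SampleRecord]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "sex": s.sex,
                "generation": s.generation,
                "bw8": "NA" if s.bw8 is None else f"{s.bw8:.4f}",
                "line": s.line,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Pedigree table with columns sample_id, sire_id, dam_id, generation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "sire_id", "dam_id", "generation"}
    if not need <= set(df.columns):
        raise ValueError(f"pedigree table lacks columns {sorted(need - set(df.columns))}")
    df["generation"] = df["generation"].astype(int)
    return df


def read_conservation(path: str | Path) -> pd.DataFrame:
    """Per-marker conservation scores: columns marker_id, phylop."""
    df = pd.read_csv(path, sep="\t")
    if not {"marker_id", "phylop"} <= set(df.columns):
        raise ValueError("conservation table needs marker_id and phylop columns")
    return df


def read_ancestry_labels(path: str | Path) -> pd.DataFrame:
    """Ancestry painting labels: sample_id, chrom, start, end, hap, donor."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor": str})
    need = {"sample_id", "chrom", "start", "end", "hap", "donor"}
    if not need <= set(df.columns):
        raise ValueError(f"ancestry table lacks columns {sorted(need - set(df.columns))}")
    return df


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    genotypes: GenotypeMatrix,
    marker: str,
    subset: Sequence[str] | None = None,
) -> tuple[float, float, dict[int, int]]:
    """Reference/alternative allele frequencies and genotype counts.

    Returns ``(ref_freq, alt_freq, counts)`` where ``counts`` maps
    genotype (ALT count) to the number of non-missing samples.
    """
    col = genotypes.column(marker)
    if subset is not None:
        col = col[[genotypes.sample_index(s) for s in subset]]
    col = col[col != MISSING]
    if len(col) == 0:
        raise ValueError(f"all calls missing at {marker}; frequency uncomputable")
    counts = {g: int(np.sum(col == g)) for g in (0, 1, 2)}
    alt = (counts[1] + 2 * counts[2]) / (2 * len(col))
    return 1.0 - alt, alt, counts
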