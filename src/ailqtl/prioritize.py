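"""Candidate-variant screen: association strength x conservation x MAF.

Candidates combine a scan's -log10 p with a per-marker conservation
(phyloP) score, minor-allele frequency and the snpEff effect category.
The screen keeps markers with MAF above a floor and phyloP in the top
q of the score distribution (nearest-rank percentile over the supplied
score universe — the analyzed region by default, a genome-wide score
table if provided), sorted by association p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CandidateRow:
    marker_id: str
    pos: int
    ref: str
    alt: str
    neglog10p: float
    phylop: float
    aaf: float
    effect_category: str = ""
    gene_name: str = ""
    transcript_change: str = ""
    protein_change: str = ""

    @property
    def maf(self) -> float:
        return min(self.aaf, 1.0 - self.aaf)


def conservation_percentile_threshold(scores: Sequence[float], q: float = 0.05) -> float:
    """Score value such that a fraction q of scores is >= it (nearest rank)."""
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) == 0:
        raise ValueError("no finite conservation scores")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = math.ceil(q * len(arr))
    return float(np.sort(arr)[::-1][k - 1])


def candidate_filter(
    rows: Sequence[CandidateRow],
    maf_min: float = 0.1,
    phylop_q: float = 0.05,
    score_universe: Sequence[float] | None = None,
) -> list[CandidateRow]:
    """Keep rows with MAF > maf_min and phyloP in the top phylop_q.

    The percentile threshold is computed over ``score_universe`` when
    given (e.g. genome-wide scores), else over the input rows' own
    scores.  Output is sorted by ascending p (descending -log10 p),
    ties by position.  Idempotent; empty results are allowed.
    """
    rows = list(rows)
    if not rows:
        return []
    universe = score_universe if score_universe is not None else [r.phylop for r in rows]
    thr = conservation_percentile_threshold(universe, phylop_q)
    kept = [r for r in rows if r.maf > maf_min and np.isfinite(r.phylop) and r.phylop >= thr]
    kept.sort(key=lambda r: (-r.neglog10p, r.pos))
    return kept


def missense_table(
    rows: Sequence[CandidateRow],
    phylop_q: float = 0.05,
    score_universe: Sequence[float] | None = None,
) -> list[CandidateRow]:
    """Missense variants passing the top-q conservation cut, in p order."""
    rows = list(rows)
    if not rows:
        return []
    universe = score_universe if score_universe is not None else [r.phylop for r in rows]
    thr = conservation_percentile_threshold(universe, phylop_q)
    kept = [
        r
        for r in rows
        if r.effect_category == "missense_variant" and np.isfinite(r.phylop) and r.phylop >= thr
    ]
    kept.sort(key=lambda r: (-r.neglog10p, r.pos))
    return kept


def build_candidate_rows(
    scan: pd.DataFrame,
    annotations,
    conservation: pd.DataFrame | None = None,
) -> list[CandidateRow]:
    """Join a scan table with annotations (and optional phyloP table).

    ``scan`` needs marker_id, pos, neglog10p (ref/alt optional);
    ``annotations`` is the AnnotatedVariant list from :func:`read_vcf`;
    ``conservation`` (marker_id, phylop) overrides annotation phyloP.
    """
    ann_by_id = {a.marker_id: a for a in annotations}
    phylop_by_id = (
        dict(zip(conservation["marker_id"], conservation["phylop"]))
        if conservation is not None
        else {}
    )
    rows = []
    for _, r in scan.iterrows():
        a = ann_by_id.get(r["marker_id"])
        if a is None:
            continue
        phylop = phylop_by_id.get(r["marker_id"], a.phylop)
        rows.append(
            CandidateRow(
                marker_id=str(r["marker_id"]),
                pos=int(r["pos"]) if "pos" in r else 0,
                ref=str(r.get("ref", "")),
                alt=str(r.get("alt", "")),
                neglog10p=float(r["neglog10p"]),
                phylop=float(phylop),
                aaf=float(a.aaf),
                effect_category=a.effect_category,
                gene_name=a.gene_name,
                transcript_change=a.transcript_change,
                protein_change=a.protein_change,
            )
        )
    return rows


def candidate_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in rows],
            "pos": [r.pos for r in rows],
            "ref": [r.ref for r in rows],
            "alt": [r.alt for r in rows],
            "neglog10p": [r.neglog10p for r in rows],
            "phylop": [r.phylop for r in rows],
            "aaf": [r.aaf for r in rows],
            "maf": [r.maf for r in rows],
            "effect": [r.effect_category for r in rows],
            "gene_name": [r.gene_name for r in rows],
            "transcript_change": [r.transcript_change for r in rows],
            "protein_change": [r.protein_change for r in rows],
        }
    )
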