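"""Copy-number segment categorisation, gene annotation, and CNA Jaccard.

Segments carry an integer total copy number (Facets-style output); the
category rule is: deletion (cn = 0), loss (cn = 1), focal amplification
(cn >= 7 on less than 5 Mb), amplification (cn >= 7 otherwise), gain
(2 <= cn < 7).  Read literally the gain band includes the diploid state,
which would label every normal segment a gain; by default cn equal to
``neutral_cn`` (2) is reported as neutral and excluded from alteration
sets, with ``as_printed=True`` restoring the literal rule.

Coordinates are 1-based with half-open [start, end) intervals; segment
length is end - start.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .variants import jaccard_distance, pairwise_jaccard_matrix  # shared contract

CATEGORIES = ("deletion", "loss", "neutral", "gain", "amplification", "focal_amplification")

FOCAL_THRESHOLD = 5_000_000

#: most extreme category wins when several segments overlap one gene
_SEVERITY = {
    "focal_amplification": 5,
    "amplification": 4,
    "gain": 3,
    "deletion": 2,
    "loss": 1,
    "neutral": 0,
}


def classify_segment(
    total_cn: int,
    length: int,
    focal_threshold: int = FOCAL_THRESHOLD,
    neutral_cn: int = 2,
    as_printed: bool = False,
) -> str:
    """Category of one segment from (total_cn, length).

    The focality boundary is strict: length exactly ``focal_threshold``
    is a (broad) amplification.
    """
    if total_cn < 0:
        raise ValueError("total_cn must be >= 0")
    if length <= 0:
        raise ValueError("segment length must be positive")
    if total_cn == 0:
        return "deletion"
    if total_cn == 1:
        return "loss"
    if total_cn >= 7:
        return "focal_amplification" if length < focal_threshold else "amplification"
    if not as_printed and total_cn == neutral_cn:
        return "neutral"
    return "gain"


def classify_segments(segments: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vector version over a SEG-like table (sample, chrom, start, end, total_cn)."""
    out = segments.copy()
    out["category"] = [
        classify_segment(cn, end - start, **kwargs)
        for cn, start, end in zip(out["total_cn"], out["start"], out["end"])
    ]
    return out


def annotate_genes(segments: pd.DataFrame, gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Gene-level CNA calls by interval overlap.

    A gene inherits the category of any overlapping non-neutral segment
    (>= 1 shared base under half-open intervals); when several segments
    overlap, the most extreme category wins
    (focal_amplification > amplification > gain; deletion > loss).
    Returns columns (sample, gene, category); insensitive to the order
    of the input segments.
    """
    classified = segments if "category" in segments.columns else classify_segments(segments)
    rows = []
    for sample, grp in classified.groupby("sample", sort=True):
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, cat in zip(grp["chrom"], grp["start"], grp["end"], grp["category"]):
            if cat == "neutral":
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end, cat)
        for gene, chrom, gstart, gend in zip(
            gene_intervals["gene"], gene_intervals["chrom"],
            gene_intervals["start"], gene_intervals["end"],
        ):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = [iv.data for iv in tree.overlap(gstart, gend)]
            if hits:
                best = max(hits, key=lambda c: _SEVERITY[c])
                rows.append((sample, gene, best))
    out = pd.DataFrame(rows, columns=["sample", "gene", "category"])
    return out.sort_values(["sample", "gene"]).reset_index(drop=True)


def cna_alteration_sets(
    gene_calls: pd.DataFrame | None = None,
    segments: pd.DataFrame | None = None,
    bin_size: int | None = None,
) -> dict[str, set]:
    """Per-sample alteration sets for Jaccard comparison.

    Default resolution is gene-level (gene, category) pairs from
    ``annotate_genes`` output; alternatively segments are discretised
    into fixed ``bin_size`` windows yielding (chrom, bin, category)
    elements.
    """
    sets: dict[str, set] = {}
    if gene_calls is not None:
        for sample, grp in gene_calls.groupby("sample", sort=True):
            sets[sample] = set(zip(grp["gene"], grp["category"]))
        return sets
    if segments is None or bin_size is None:
        raise ValueError("provide gene_calls, or segments with bin_size")
    classified = segments if "category" in segments.columns else classify_segments(segments)
    for sample, grp in classified.groupby("sample", sort=True):
        elems = set()
        for chrom, start, end, cat in zip(grp["chrom"], grp["start"], grp["end"], grp["category"]):
            if cat == "neutral":
                continue
            for b in range((start - 1) // bin_size, (end - 2) // bin_size + 1):
                elems.add((chrom, b, cat))
        sets[sample] = elems
    return sets


def cna_jaccard(sets_a: set, sets_b: set) -> float:
    """Jaccard distance between two alteration-element sets."""
    return jaccard_distance(sets_a, sets_b)


def cna_jaccard_matrix(sample_sets: dict[str, set]) -> pd.DataFrame:
    return pairwise_jaccard_matrix(sample_sets)
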