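"""Multi-caller fusion consensus, junction-read validation, and annotation.

Candidate fusions from up to five callers are grouped by ordered gene
pair (5' partner, 3' partner) per sample and kept when at least three
distinct tools agree.  Candidates are then validated against a
junction-read evidence table (FusionInspector-style re-alignment
output): a fusion is real when at least one read covers the breakpoint.
Validation re-searches every sample of the cohort, so a key validated
anywhere can be rescued in samples where the initial callers missed it.

Fusion keys match on the gene pair only — per-tool breakpoint
coordinates routinely disagree by a few bases, so the consensus
breakpoint is reported as the median position per side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import classify_origin

DEFAULT_TOOLS = ("arriba", "ericscript", "pizzly", "squid", "starfusion")

KEY = ["sample", "gene5", "gene3"]


def consensus_filter(
    calls: pd.DataFrame,
    min_tools: int = 3,
    known_tools: tuple[str, ...] = DEFAULT_TOOLS,
) -> pd.DataFrame:
    """Group per-tool calls by (sample, gene5, gene3); keep >= min_tools.

    A tool reporting the same key twice counts once.  Output is sorted
    and therefore invariant to input row order and duplicated rows.
    Columns: sample, gene5, gene3, supporting_tools (comma-joined),
    n_tools, median breakpoints per side.
    """
    unknown = set(calls["tool"]) - set(known_tools)
    if unknown:
        raise ValueError(f"unknown tool name(s): {sorted(unknown)}")
    rows = []
    for (sample, g5, g3), grp in calls.groupby(KEY, sort=True):
        tools = sorted(set(grp["tool"]))
        if len(tools) < min_tools:
            continue
        rows.append(
            {
                "sample": sample,
                "gene5": g5,
                "gene3": g3,
                "supporting_tools": ",".join(tools),
                "n_tools": len(tools),
                "chrom5": grp["chrom5"].iloc[0],
                "pos5": int(np.median(grp["pos5"])),
                "strand5": grp["strand5"].iloc[0],
                "chrom3": grp["chrom3"].iloc[0],
                "pos3": int(np.median(grp["pos3"])),
                "strand3": grp["strand3"].iloc[0],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "gene5", "gene3", "supporting_tools", "n_tools",
                 "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3"],
    )


def validate_breakpoint(
    candidates: pd.DataFrame,
    evidence: pd.DataFrame,
    min_junction_reads: int = 1,
    rescue: bool = True,
) -> pd.DataFrame:
    """Junction-read validation with cross-sample rescue.

    ``evidence`` has columns (sample, gene5, gene3, junction_reads); a
    key missing from it counts as 0 reads.  A candidate is validated iff
    junction_reads >= min_junction_reads in its sample.  With
    ``rescue``, every gene pair validated in any sample is additionally
    looked up in every other sample's evidence, marking it present where
    supported — rescue adds sample-presence, never new gene pairs.
    Returns columns (sample, gene5, gene3, junction_reads, rescued).
    """
    ev = evidence.set_index(KEY)["junction_reads"].to_dict()

    validated = []
    for sample, g5, g3 in candidates[KEY].itertuples(index=False):
        jr = ev.get((sample, g5, g3), 0)
        if jr >= min_junction_reads:
            validated.append({"sample": sample, "gene5": g5, "gene3": g3,
                              "junction_reads": jr, "rescued": False})
    out = pd.DataFrame(validated, columns=["sample", "gene5", "gene3", "junction_reads", "rescued"])
    if rescue and not out.empty:
        seen = set(map(tuple, out[KEY].itertuples(index=False)))
        validated_pairs = set(zip(out["gene5"], out["gene3"]))
        extra = []
        for (sample, g5, g3), jr in ev.items():
            if (g5, g3) in validated_pairs and (sample, g5, g3) not in seen \
                    and jr >= min_junction_reads:
                extra.append({"sample": sample, "gene5": g5, "gene3": g3,
                              "junction_reads": jr, "rescued": True})
        if extra:
            out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out.sort_values(KEY).reset_index(drop=True)


# ---------------------------------------------------------------------------
# fusion-type annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: strand and ordered exon spans (1-based half-open)."""

    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    def last_exon(self) -> tuple[int, int]:
        """Exon containing the transcription end (strand-aware)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


def _retained_fraction_5prime(bp: int, model: GeneModel) -> float:
    """Fraction of the gene span the 5' partner contributes (up to bp)."""
    if model.strand == "+":
        kept = bp - model.start
    else:
        kept = model.end - bp
    return float(np.clip(kept / model.span, 0.0, 1.0))


def _retained_fraction_3prime(bp: int, model: GeneModel) -> float:
    """Fraction of the gene span the 3' partner contributes (from bp on)."""
    if model.strand == "+":
        kept = model.end - bp
    else:
        kept = bp - model.start
    return float(np.clip(kept / model.span, 0.0, 1.0))


def annotate_fusion_type(
    pos5: int,
    pos3: int,
    model5: GeneModel | None,
    model3: GeneModel | None,
    altered_threshold: float = 0.5,
) -> str:
    """Assign 3'-altered / 5'-altered / truncated from breakpoint geometry.

    Declared interpretation (the category names come from the study, the
    definitions are ours): *truncated* when the 3'-partner breakpoint
    falls in its last exon, leaving no downstream continuation; else
    *5'-altered* when the 5' partner contributes less than
    ``altered_threshold`` of its span; else *3'-altered* when the 3'
    partner does; when both or neither side crosses the threshold, the
    side losing the larger fraction is called altered (tie -> 3'-altered).
    Unknown gene models yield "unclassified".
    """
    if model5 is None or model3 is None:
        return "unclassified"
    lo, hi = model3.last_exon()
    if lo <= pos3 < hi:
        return "truncated"
    frac5 = _retained_fraction_5prime(pos5, model5)
    frac3 = _retained_fraction_3prime(pos3, model3)
    five_altered = frac5 < altered_threshold
    three_altered = frac3 < altered_threshold
    if five_altered and not three_altered:
        return "5'-altered"
    if three_altered and not five_altered:
        return "3'-altered"
    return "5'-altered" if frac5 < frac3 else "3'-altered"


def annotate_fusions(
    fusions: pd.DataFrame, gene_models: dict[str, GeneModel], **kwargs
) -> pd.DataFrame:
    out = fusions.copy()
    out["category"] = [
        annotate_fusion_type(p5, p3, gene_models.get(g5), gene_models.get(g3), **kwargs)
        for g5, g3, p5, p3 in zip(out["gene5"], out["gene3"], out["pos5"], out["pos3"])
    ]
    return out


def conservation_counts(
    validated: pd.DataFrame, sample_meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal conservation of validated fusions.

    ``sample_meta`` maps sample -> (patient, timepoint).  Returns
    (per_fusion, summary): per (patient, gene5, gene3) the timepoints of
    presence and origin class (same rules as variant conservation), and
    per-patient counts of diagnosis->PDX conserved, relapse->PDX
    conserved, and non-conserved fusions.
    """
    meta = sample_meta.set_index("sample")
    rows = []
    merged = validated.join(meta, on="sample")
    for (patient, g5, g3), grp in merged.groupby(["patient", "gene5", "gene3"], sort=True):
        present = set(grp["timepoint"])
        rows.append(
            {
                "patient": patient,
                "gene5": g5,
                "gene3": g3,
                "present_in": ",".join(sorted(present)),
                "origin": classify_origin(present),
            }
        )
    per_fusion = pd.DataFrame(rows, columns=["patient", "gene5", "gene3", "present_in", "origin"])
    if per_fusion.empty:
        summary = pd.DataFrame(columns=["patient", "diagnosis_to_pdx", "relapse_to_pdx", "not_conserved"])
    else:
        counts = per_fusion.groupby("patient")["origin"].value_counts().unstack(fill_value=0)
        summary = pd.DataFrame(
            {
                "patient": counts.index,
                "diagnosis_to_pdx": counts.get("diagnosis-conserved", 0),
                "relapse_to_pdx": counts.get("relapse-emergent", 0),
                "not_conserved": counts.get("not-conserved", 0) + counts.get("pdx-private", 0),
            }
        ).reset_index(drop=True)
    return per_fusion, summary
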