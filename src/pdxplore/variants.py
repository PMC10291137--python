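"""Somatic-variant filtering, Jaccard similarity, and longitudinal conservation.

Somatic calls (Varscan2-style tables) are filtered on three evidence
rules — minimum supporting reads, minimum variant allele fraction, and
maximum population allele frequency in two databases — then compared
across timepoints (diagnosis, relapse, PDX) with the Jaccard distance
on variant-key sets, and classified by longitudinal origin
(diagnosis-conserved, relapse-emergent, pdx-private).

Boundary conventions: the removal rules are strict ("less than five
reads", "more than 1% of the population"), so alt_reads == 5 and
popaf == 0.01 are kept; vaf >= 0.05 is kept.  A missing population
frequency counts as 0 unless ``strict_popaf`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TIMEPOINTS = ("diagnosis", "relapse", "pdx_sc", "pdx_pt")
PDX_TIMEPOINTS = ("pdx_sc", "pdx_pt")

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

ORIGINS = ("diagnosis-conserved", "relapse-emergent", "pdx-private", "not-conserved")


@dataclass(frozen=True)
class FilterThresholds:
    min_alt_reads: int = 5
    min_vaf: float = 0.05
    max_popaf: float = 0.01
    strict_popaf: bool = False  # reject calls with missing population AFs

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf <= 1 or not 0 < self.max_popaf <= 1:
            raise ValueError("proportion thresholds must be in (0, 1]")


EVIDENCE_FIELDS = ["alt_reads", "vaf", "popaf_1000g", "popaf_kaviar"]


def filter_variants(
    calls: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three somatic filter rules.

    A call is kept iff alt_reads >= min_alt_reads AND vaf >= min_vaf AND
    both population allele frequencies <= max_popaf.  Returns
    ``(kept, rejection_log)``; the log lists the failed rule(s) per
    dropped call as a comma-joined string in ``failed_rules``.  Calls
    with missing evidence fields are rejected with reason "incomplete",
    never silently kept.
    """
    t = thresholds or FilterThresholds()
    calls = calls.copy()
    popafs = calls[["popaf_1000g", "popaf_kaviar"]]
    if not t.strict_popaf:
        popafs = popafs.fillna(0.0)
    incomplete = calls[["alt_reads", "vaf"]].isna().any(axis=1) | popafs.isna().any(axis=1)

    fail_support = calls["alt_reads"] < t.min_alt_reads
    fail_vaf = calls["vaf"] < t.min_vaf
    fail_pop = (popafs["popaf_1000g"] > t.max_popaf) | (popafs["popaf_kaviar"] > t.max_popaf)

    reasons = []
    for inc, fs, fv, fp in zip(incomplete, fail_support, fail_vaf, fail_pop):
        if inc:
            reasons.append("incomplete")
            continue
        fired = [name for name, f in (("support", fs), ("vaf", fv), ("population", fp)) if f]
        reasons.append(",".join(fired))
    reasons = pd.Series(reasons, index=calls.index)
    kept = calls[reasons == ""].copy()
    log = calls[reasons != ""].copy()
    log["failed_rules"] = reasons[reasons != ""]
    return kept, log


def variant_key_sets(calls: pd.DataFrame, by_gene: bool = False) -> dict[str, set]:
    """Per-sample sets of variant identities.

    Default identity is the (chrom, pos, ref, alt) tuple; ``by_gene``
    collapses to gene symbols instead.
    """
    out: dict[str, set] = {}
    for sample, grp in calls.groupby("sample", sort=True):
        if by_gene:
            out[sample] = set(grp["gene"])
        else:
            out[sample] = set(map(tuple, grp[VARIANT_KEY].itertuples(index=False)))
    return out


def jaccard_distance(set_a: set, set_b: set) -> float:
    """d = 1 - |A∩B| / |A∪B|, with d(∅, ∅) = 0."""
    union = set_a | set_b
    if not union:
        return 0.0
    return 1.0 - len(set_a & set_b) / len(union)


def pairwise_jaccard_matrix(sample_sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric Jaccard-distance matrix over >= 2 sample sets."""
    if len(sample_sets) < 2:
        raise ValueError("need at least two samples")
    names = sorted(sample_sets)
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            d = jaccard_distance(sample_sets[a], sample_sets[names[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def classify_origin(present_in: set[str]) -> str:
    """Longitudinal origin of one alteration from its presence pattern.

    diagnosis-conserved: at diagnosis and in >= 1 PDX;
    relapse-emergent: absent at diagnosis, at relapse and in >= 1 PDX;
    pdx-private: only in PDX sample(s); otherwise not-conserved.
    """
    unknown = present_in - set(TIMEPOINTS)
    if unknown:
        raise ValueError(f"unknown timepoint label(s): {sorted(unknown)}")
    in_pdx = bool(present_in & set(PDX_TIMEPOINTS))
    if "diagnosis" in present_in and in_pdx:
        return "diagnosis-conserved"
    if "relapse" in present_in and in_pdx:
        return "relapse-emergent"
    if present_in <= set(PDX_TIMEPOINTS) and present_in:
        return "pdx-private"
    return "not-conserved"


def classify_conservation(calls: pd.DataFrame) -> pd.DataFrame:
    """ConservationRecord table for every (patient, variant key).

    Requires >= 2 timepoints per patient.  Each record carries the set of
    timepoints the variant is present in and its origin class.
    """
    records = []
    for patient, grp in calls.groupby("patient", sort=True):
        if grp["timepoint"].nunique() < 2:
            raise ValueError(f"patient {patient} has < 2 timepoints")
        for key, kgrp in grp.groupby(VARIANT_KEY, sort=True):
            present = set(kgrp["timepoint"])
            records.append(
                {
                    "patient": patient,
                    "gene": kgrp["gene"].iloc[0],
                    "chrom": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "present_in": ",".join(tp for tp in TIMEPOINTS if tp in present),
                    "origin": classify_origin(present),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["patient", "gene", "chrom", "pos", "ref", "alt", "present_in", "origin"],
    )


def mutation_gain_ratio(
    sample_sets: dict[str, set],
    patients: pd.DataFrame,
    earlier: str = "diagnosis",
    later: str = "relapse",
) -> pd.DataFrame:
    """Per-patient |later| / |earlier| variant-count ratio.

    ``patients`` maps sample -> (patient, timepoint) (columns sample,
    patient, timepoint).  An empty earlier set yields a missing ratio.
    The cohort mean and standard deviation are the summary the study
    reports as "x-fold more new mutations".
    """
    ix = patients.set_index("sample")
    rows = []
    for patient, grp in ix.groupby("patient"):
        by_tp = {tp: s for s, tp in zip(grp.index, grp["timepoint"])}
        if earlier not in by_tp or later not in by_tp:
            continue
        n_early = len(sample_sets.get(by_tp[earlier], set()))
        n_late = len(sample_sets.get(by_tp[later], set()))
        ratio = n_late / n_early if n_early else np.nan
        rows.append({"patient": patient, "n_earlier": n_early, "n_later": n_late, "ratio": ratio})
    return pd.DataFrame(rows, columns=["patient", "n_earlier", "n_later", "ratio"])


def oncoprint_table(
    gene_panel: list[str],
    mutations: pd.DataFrame | None = None,
    cna_calls: pd.DataFrame | None = None,
    fusions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene x sample grid of alteration classes.

    Cells hold semicolon-joined labels ("mut", CNA category, "fusion");
    genes outside the panel are excluded.  Inputs are the kept-variant
    table (columns gene, sample), gene-level CNA calls (gene, sample,
    category), and validated fusions (gene5, gene3, sample).
    """
    if not gene_panel:
        raise ValueError("gene panel must be nonempty")
    cells: dict[tuple[str, str], list[str]] = {}
    samples: set[str] = set()

    def _add(gene, sample, label):
        samples.add(sample)
        if gene in panel_set:
            cells.setdefault((gene, sample), []).append(label)

    panel_set = set(gene_panel)
    if mutations is not None:
        for gene, sample in zip(mutations["gene"], mutations["sample"]):
            _add(gene, sample, "mut")
    if cna_calls is not None:
        for gene, sample, cat in zip(cna_calls["gene"], cna_calls["sample"], cna_calls["category"]):
            _add(gene, sample, cat)
    if fusions is not None:
        for g5, g3, sample in zip(fusions["gene5"], fusions["gene3"], fusions["sample"]):
            _add(g5, sample, "fusion")
            _add(g3, sample, "fusion")
    out = pd.DataFrame("", index=list(gene_panel), columns=sorted(samples))
    for (gene, sample), labels in cells.items():
        out.loc[gene, sample] = ";".join(sorted(set(labels)))
    return out
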