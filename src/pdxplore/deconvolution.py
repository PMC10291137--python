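"""Tumor / microenvironment expression deconvolution via the PDX human fraction.

In a PDX, the human fraction of the transcriptome comes from tumor
cells only — the microenvironment (stroma, vessels, immune cells) is
mouse.  Genes expressed in patient tumors but absent from the PDX human
fraction are therefore microenvironment (ME) genes; removing them from
the human matrices leaves the tumor-cell expression program, and their
mouse orthologs in the PDX mouse fraction give a cross-species view of
the microenvironment itself.

The ME call combines an absence rule (normalized mean in the PDX human
fraction at most ``absent_max_mean`` counts) with an explicit
negative-binomial rate comparison between patient and PDX-human groups
(method-of-moments dispersion, Wald test on the log-rate difference,
Benjamini-Hochberg correction) and a minimum patient/PDX fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDO = 0.5  # continuity correction for zero-count groups


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def normalize_counts(counts: pd.DataFrame, target: float | None = None) -> pd.DataFrame:
    """Scale each sample to a common library size (default: the mean).

    Keeping the count scale (rather than per-million) makes absolute
    thresholds like "fewer than 3 reads" meaningful after normalization.
    """
    lib = library_sizes(counts)
    target = float(lib.mean()) if target is None else target
    return counts * (target / lib)


def cpm_log1p(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p counts-per-million, the transform used before any PCA."""
    lib = library_sizes(counts)
    return np.log1p(counts * 1e6 / lib)


def _nb_group_stats(counts: np.ndarray, size_factors: np.ndarray):
    """Rate estimate and per-gene normalized moments for one group."""
    q = counts.sum(axis=1) / size_factors.sum()
    norm = counts / size_factors
    return q, norm.mean(axis=1), norm.var(axis=1, ddof=1)


def nb_rate_test(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame
) -> pd.DataFrame:
    """Wald test of equal negative-binomial rates between two groups.

    Counts y_ij ~ NB(mean s_j q_i, var mu + phi_i mu^2) with size
    factors s_j = libsize_j / mean libsize over both groups.  The
    dispersion phi_i is a pooled method-of-moments estimate from the
    normalized within-group moments; the statistic is the
    continuity-corrected log-rate difference over its delta-method
    standard error.  Returns per-gene (mean_a, mean_b, log2_fold,
    p_value) on the normalized-count scale.
    """
    genes = counts_a.index
    lib = np.concatenate([library_sizes(counts_a), library_sizes(counts_b)])
    mean_lib = lib.mean()
    sa = library_sizes(counts_a).to_numpy() / mean_lib
    sb = library_sizes(counts_b).to_numpy() / mean_lib
    ya, yb = counts_a.to_numpy(float), counts_b.to_numpy(float)

    qa, ma, va = _nb_group_stats(ya, sa)
    qb, mb, vb = _nb_group_stats(yb, sb)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_a = (va - ma) / ma**2
        phi_b = (vb - mb) / mb**2
    phi = np.nanmean(np.stack([phi_a, phi_b]), axis=0)
    phi = np.clip(np.nan_to_num(phi, nan=0.0), 0.0, None)

    def _var_log_q(q, s, phi):
        qc = q + PSEUDO / s.sum()          # continuity-corrected rate, (G,)
        mu = np.outer(qc, s)               # expected counts, (G, S)
        var_q = (mu + phi[:, None] * mu**2).sum(axis=1) / s.sum() ** 2
        return var_q / qc**2, qc

    v_log_a, qac = _var_log_q(qa, sa, phi)
    v_log_b, qbc = _var_log_q(qb, sb, phi)
    z = (np.log(qac) - np.log(qbc)) / np.sqrt(v_log_a + v_log_b)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "mean_a": ma,  # normalized-count scale (mean library size)
            "mean_b": mb,
            "log2_fold": np.log2((ma + PSEUDO) / (mb + PSEUDO)),
            "z": z,
            "p_value": p,
        },
        index=genes,
    )


@dataclass
class MeGeneResult:
    me_genes: set[str]
    table: pd.DataFrame        # per-gene decision trace
    tumor_matrix: pd.DataFrame  # patient + pdx_human samples, ME genes removed
    excluded_all_zero: list[str]


def identify_me_genes(
    patient_counts: pd.DataFrame,
    pdx_human_counts: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float = 4.0,
    absent_max_mean: float = 3.0,
) -> MeGeneResult:
    """Call microenvironment genes from the patient vs PDX-human contrast.

    A gene is ME iff its normalized mean in the PDX human fraction is at
    most ``absent_max_mean`` counts AND the NB rate test rejects
    equality at BH-adjusted ``alpha`` with patient/PDX fold at least
    ``min_fold``.  All-zero genes are excluded from testing and
    reported.  The returned tumor matrix is the column-concatenated
    human matrix with ME genes removed.
    """
    if patient_counts.shape[1] < 2 or pdx_human_counts.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if not patient_counts.index.equals(pdx_human_counts.index):
        raise ValueError("gene universes differ between groups")

    total = patient_counts.sum(axis=1) + pdx_human_counts.sum(axis=1)
    all_zero = total[total == 0].index.tolist()
    pat = patient_counts.drop(index=all_zero)
    pdx = pdx_human_counts.drop(index=all_zero)

    res = nb_rate_test(pat, pdx)
    res = res.rename(columns={"mean_a": "mean_patient", "mean_b": "mean_pdx_human"})
    reject, padj, _, _ = multipletests(res["p_value"], alpha=alpha, method="fdr_bh")
    res["p_adj"] = padj
    fold = (res["mean_patient"] + PSEUDO) / (res["mean_pdx_human"] + PSEUDO)
    res["fold"] = fold
    res["absent_in_pdx"] = res["mean_pdx_human"] <= absent_max_mean
    res["is_me"] = res["absent_in_pdx"] & reject & (fold >= min_fold) & (res["z"] > 0)

    me = set(res.index[res["is_me"]])
    full = pd.concat([patient_counts, pdx_human_counts], axis=1)
    tumor = full.drop(index=sorted(me))
    return MeGeneResult(me_genes=me, table=res, tumor_matrix=tumor, excluded_all_zero=all_zero)


def build_tumor_matrix(human_counts: pd.DataFrame, me_genes: set[str]) -> pd.DataFrame:
    """Drop ME genes from a human count matrix; the rest is the tumor."""
    unknown = me_genes - set(human_counts.index)
    if unknown:
        raise ValueError(f"ME genes outside the matrix universe: {sorted(unknown)[:5]}...")
    out = human_counts.drop(index=sorted(me_genes))
    if out.empty:
        import warnings

        warnings.warn("all genes were removed as microenvironment", stacklevel=2)
    return out


def mouse_absent_genes(pdx_mouse_counts: pd.DataFrame, max_reads: int = 3) -> set[str]:
    """Mouse genes with fewer than ``max_reads`` reads in every sample."""
    return set(pdx_mouse_counts.index[(pdx_mouse_counts < max_reads).all(axis=1)])


def build_cross_species_me_matrix(
    patient_me_counts: pd.DataFrame,
    pdx_mouse_counts: pd.DataFrame,
    ortholog_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge human ME genes with their mouse orthologs into one matrix.

    The ortholog map (columns human_gene, mouse_gene) is reduced to 1:1
    pairs; many-to-many entries are dropped and reported.  Each species
    group is library-size normalized (CPM, log1p) then per-gene
    standardized within the group before merging — the scaling step
    that puts the two sample natures on one axis.  Returns
    ``(merged, dropped)`` with merged rows indexed by human gene and a
    report of dropped genes with reasons.
    """
    counts = ortholog_map.groupby("human_gene")["mouse_gene"].nunique()
    multi_h = set(counts[counts > 1].index)
    counts_m = ortholog_map.groupby("mouse_gene")["human_gene"].nunique()
    multi_m = set(counts_m[counts_m > 1].index)
    clean = ortholog_map[
        ~ortholog_map["human_gene"].isin(multi_h) & ~ortholog_map["mouse_gene"].isin(multi_m)
    ]
    m_of = dict(zip(clean["human_gene"], clean["mouse_gene"]))

    dropped = []
    keep_h, keep_m = [], []
    for g in patient_me_counts.index:
        if g in multi_h:
            dropped.append((g, "many_to_many_ortholog"))
        elif g not in m_of:
            dropped.append((g, "no_ortholog"))
        elif m_of[g] not in pdx_mouse_counts.index:
            dropped.append((g, "ortholog_not_measured"))
        else:
            keep_h.append(g)
            keep_m.append(m_of[g])
    if not keep_h:
        raise ValueError("no ME gene has a usable mouse ortholog")

    def _scale(df: pd.DataFrame) -> pd.DataFrame:
        log = cpm_log1p(df)
        sd = log.std(axis=1, ddof=0).replace(0, 1.0)
        return log.sub(log.mean(axis=1), axis=0).div(sd, axis=0)

    human_part = _scale(patient_me_counts.loc[keep_h])
    mouse_part = _scale(pdx_mouse_counts.loc[keep_m])
    mouse_part.index = keep_h  # re-key mouse rows by the human ortholog
    merged = pd.concat([human_part, mouse_part], axis=1)
    report = pd.DataFrame(dropped, columns=["gene", "reason"])
    return merged, report
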