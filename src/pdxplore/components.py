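"""PCA decomposition, component selection, loading enrichment, imputation.

The tumor and microenvironment matrices are decomposed by PCA on
gene-centered log-normalized expression.  A component is kept when it
explains more than ``min_var`` (default 5%) of the overall variance and
shows no significant separation between sample groups (patient vs PDX,
or human vs mouse) — a separating component reflects the xenograft
setting rather than biology.  Kept components are interpreted through
their gene loadings: top signed contributors and a preranked
running-sum gene-set enrichment with permutation p-values.

The proteomics helpers filter proteins by missing-value rate (the <34%
imputability rule) and complete the survivors by iterative low-rank
PCA imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REJECTION_REASONS = ("none", "low_variance", "species_separation")


@dataclass
class ComponentDecomposition:
    scores: pd.DataFrame      # sample x component
    loadings: pd.DataFrame    # gene x component
    var_fraction: np.ndarray  # per-component share of total variance
    selected: np.ndarray = field(default=None)
    rejection_reason: list[str] = field(default=None)
    separation_p_adj: np.ndarray = field(default=None)

    def __post_init__(self):
        k = self.scores.shape[1]
        if self.selected is None:
            self.selected = np.zeros(k, dtype=bool)
        if self.rejection_reason is None:
            self.rejection_reason = ["none"] * k

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)


def decompose(matrix: pd.DataFrame, n_components: int | None = None) -> ComponentDecomposition:
    """PCA of a gene x sample matrix (genes centered across samples).

    Deterministic up to sign; the sign of each component is fixed so
    that its largest-magnitude gene loading is positive.  Scores are the
    sample coordinates (U*S), loadings the orthonormal gene axes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = matrix.to_numpy(float).T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k_max = int((s > 1e-12 * max(s[0], 1e-300)).sum())
    k = min(n_components or k_max, k_max)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-|loading| gene positive per component
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    total_var = (x**2).sum()
    var_fraction = s**2 / total_var if total_var > 0 else np.zeros(k)
    names = [f"PC{j + 1}" for j in range(k)]
    return ComponentDecomposition(
        scores=pd.DataFrame(u * s, index=matrix.columns, columns=names),
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=names),
        var_fraction=var_fraction,
    )


def select_components(
    dec: ComponentDecomposition,
    group_labels: dict[str, str] | None,
    min_var: float = 0.05,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> ComponentDecomposition:
    """Apply the variance and group-separation selection rule.

    A component is rejected when its variance fraction is not strictly
    greater than ``min_var`` (reason ``low_variance``), or when a
    two-sided rank-sum test (or t-test) of its scores between the two
    sample groups is significant after BH correction across the
    variance-passing components (reason ``species_separation``).
    With no or a single group the separation test is skipped.
    Flags are written into ``dec`` and the same object returned.
    """
    k = dec.scores.shape[1]
    reason = ["none"] * k
    passing = []
    for j in range(k):
        if dec.var_fraction[j] <= min_var:
            reason[j] = "low_variance"
        else:
            passing.append(j)

    padj_full = np.full(k, np.nan)
    groups = None
    if group_labels is not None:
        labels = pd.Series({s: group_labels[s] for s in dec.scores.index})
        uniq = sorted(labels.unique())
        if len(uniq) == 2:
            groups = [dec.scores.index[labels == g] for g in uniq]
    if passing and groups is not None:
        pvals = []
        for j in passing:
            a = dec.scores.iloc[:, j].loc[groups[0]]
            b = dec.scores.iloc[:, j].loc[groups[1]]
            if test == "ranksum":
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            else:
                p = stats.ttest_ind(a, b).pvalue
            pvals.append(p)
        rej, padj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for j, r, pa in zip(passing, rej, padj):
            padj_full[j] = pa
            if r:
                reason[j] = "species_separation"
    dec.selected = np.array([r == "none" for r in reason])
    dec.rejection_reason = reason
    dec.separation_p_adj = padj_full
    return dec


def top_contributors(loadings: pd.DataFrame, component: str, n: int) -> pd.DataFrame:
    """The n genes of largest |loading| on one component, with signs.

    Ties in |loading| are broken by gene id (lexicographic), so the
    output is fully deterministic.
    """
    col = loadings[component]
    if n > len(col):
        raise ValueError("n exceeds gene count")
    order = sorted(col.index, key=lambda g: (-abs(col[g]), g))[:n]
    return pd.DataFrame(
        {
            "gene": order,
            "loading": [col[g] for g in order],
            "sign": ["+" if col[g] >= 0 else "-" for g in order],
        }
    )


# ---------------------------------------------------------------------------
# preranked loading enrichment
# ---------------------------------------------------------------------------

def _enrichment_score(ranked_weights: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum score.

    Genes are walked in rank order; hits step up by |weight| (normalized),
    misses step down by 1/(N - Nh); the score is the running-sum value of
    largest magnitude (signed).
    """
    n = len(ranked_weights)
    nh = int(in_set.sum())
    w = np.abs(ranked_weights) * in_set
    wsum = w.sum()
    if wsum == 0:  # no hit carries weight: fall back to unweighted hits
        w = in_set.astype(float)
        wsum = w.sum()
    steps = np.where(in_set, w / wsum, -1.0 / (n - nh))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def loading_enrichment(
    loadings: pd.Series,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Preranked gene-set enrichment on one component's signed loadings.

    Genes are ranked by signed loading (descending); the enrichment
    score is the weighted running-sum statistic with weight |loading|;
    the null is gene-label permutation; p = (1 + #{|ES_perm| >= |ES|})
    / (1 + n_perm), BH-corrected across sets.  Sets overlapping the
    universe in fewer than ``min_set_size`` genes are skipped and
    reported with NaN scores.
    """
    rng = np.random.default_rng(seed)
    order = loadings.sort_values(ascending=False, kind="mergesort")
    universe = list(order.index)
    weights = order.to_numpy()
    n = len(universe)
    pos = {g: i for i, g in enumerate(universe)}

    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & set(universe)
        if len(members) < min_set_size:
            rows.append({"gene_set": name, "es": np.nan, "p_value": np.nan,
                         "p_adj": np.nan, "direction": "skipped", "set_size": len(members)})
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[[pos[g] for g in members]] = True
        es = _enrichment_score(weights, in_set)
        null = np.empty(n_perm)
        idx = np.flatnonzero(in_set)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=len(idx), replace=False)] = True
            null[b] = _enrichment_score(weights, perm)
        p = (1 + int((np.abs(null) >= abs(es)).sum())) / (1 + n_perm)
        rows.append({"gene_set": name, "es": es, "p_value": p, "p_adj": np.nan,
                     "direction": "positive" if es >= 0 else "negative",
                     "set_size": len(members)})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    if tested.any():
        _, padj, _, _ = multipletests(out.loc[tested, "p_value"], method="fdr_bh")
        out.loc[tested, "p_adj"] = padj
    return out


# ---------------------------------------------------------------------------
# proteomics: missingness filter and PCA imputation
# ---------------------------------------------------------------------------

def filter_by_missingness(
    matrix: pd.DataFrame, max_missing: float = 0.34
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep proteins whose missing-value fraction is below ``max_missing``.

    Returns (kept, dropped_report); report columns (protein,
    missing_fraction).
    """
    frac = matrix.isna().mean(axis=1)
    kept = matrix[frac < max_missing]
    dropped = pd.DataFrame(
        {"protein": frac.index[frac >= max_missing],
         "missing_fraction": frac[frac >= max_missing].to_numpy()}
    )
    return kept, dropped


def pca_impute(
    matrix: pd.DataFrame,
    rank: int = 2,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[pd.DataFrame, bool, int]:
    """Iterative low-rank completion of a matrix with missing cells.

    Missing cells start at their row means; each iteration fits a
    rank-``rank`` SVD to the completed, row-centered matrix and replaces
    the missing cells with the reconstruction, until the largest change
    on a missing cell drops below ``tol`` or ``max_iter`` is reached.
    Observed cells are never modified.  Returns (completed, converged,
    n_iterations).
    """
    x = matrix.to_numpy(float).copy()
    mask = np.isnan(x)
    if not mask.any():
        return matrix.copy(), True, 0
    row_means = np.nanmean(x, axis=1)
    x[mask] = np.take(row_means, np.where(mask)[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = x.mean(axis=1, keepdims=True)
        c = x - mu
        u, s, vt = np.linalg.svd(c, full_matrices=False)
        recon = mu + (u[:, :rank] * s[:rank]) @ vt[:rank]
        delta = np.max(np.abs(x[mask] - recon[mask]))
        x[mask] = recon[mask]
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"PCA imputation did not converge in {max_iter} iterations", stacklevel=2)
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns), converged, it


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
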