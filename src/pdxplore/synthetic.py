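"""Synthetic cohort generators with recorded ground truth.

Every downstream stage of the pipeline (read partitioning, variant
filtering, CNA categorisation, fusion consensus, expression
deconvolution, component selection, growth fitting) is exercised on
data produced here, so each generator plants a known structure and
returns it alongside the emitted tables:

* two-species read mixtures with per-read true class,
* clonal variant sets shared / gained across diagnosis -> relapse -> PDX,
* copy-number segment profiles with planted categories,
* multi-tool fusion tables with planted consensus survivors,
* low-rank negative-binomial expression with planted microenvironment
  (ME) genes and a planted species-separating latent factor,
* rank-deficient protein abundance matrices with missing values,
* exponential tumor-growth curves.

All generators are deterministic under a fixed seed (byte-identical
output files).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("diagnosis", "relapse", "pdx_sc", "pdx_pt")
PATIENT_TIMEPOINTS = ("diagnosis", "relapse")
PDX_TIMEPOINTS = ("pdx_sc", "pdx_pt")

#: sample-name suffix per timepoint, following the <model>_<Pat|PDX>_<D|R|sc|pt> convention
TIMEPOINT_SUFFIX = {
    "diagnosis": "Pat_D",
    "relapse": "Pat_R",
    "pdx_sc": "PDX_sc",
    "pdx_pt": "PDX_pt",
}

FUSION_TOOLS = ("arriba", "ericscript", "pizzly", "squid", "starfusion")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic patient/PDX cohort.

    Mirrors the study layout: per patient one diagnosis biopsy, one
    relapse tumor, and two derived PDX models (subcutaneous and
    paratibial), each PDX sequenced as a human (tumor) and mouse
    (microenvironment) fraction.
    """

    n_patients: int = 8
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_genes: int = 2000
    n_me_genes: int = 200
    n_variants_shared: int = 30
    n_variants_relapse_gained: int = 15
    n_variants_pdx_private: int = 5
    fusion_tool_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_me_genes >= self.n_genes:
            raise ValueError("n_me_genes must be < n_genes")
        counts = (
            self.n_patients,
            self.n_genes,
            self.n_me_genes,
            self.n_variants_shared,
            self.n_variants_relapse_gained,
            self.n_variants_pdx_private,
            self.fusion_tool_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be unique")

    @property
    def patients(self) -> list[str]:
        return [f"OS-{i + 1:02d}" for i in range(self.n_patients)]

    def sample_id(self, patient: str, timepoint: str) -> str:
        return f"{patient}_{TIMEPOINT_SUFFIX[timepoint]}"


@dataclass
class GroundTruth:
    """Planted truth for one synthetic cohort, JSON-serialisable."""

    me_gene_ids: set[str] = field(default_factory=set)
    variant_sets_per_sample: dict[str, set[tuple]] = field(default_factory=dict)
    cna_sets_per_sample: dict[str, set[tuple]] = field(default_factory=dict)
    true_fusion_survivors: set[tuple] = field(default_factory=set)
    fusion_presence: dict[tuple, set[str]] = field(default_factory=dict)
    species_factor_index: int | None = None
    factor_scores: pd.DataFrame | None = None
    td_days: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def _enc(v):
            if isinstance(v, set):
                return sorted([list(x) if isinstance(x, tuple) else x for x in v])
            if isinstance(v, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: _enc(x) for k, x in v.items()}
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="split")
            return v

        return json.dumps(
            {f.name: _enc(getattr(self, f.name)) for f in dataclasses.fields(self)},
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# two-species read mixtures
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.integers(0, 4, size=length).astype(np.uint8).tobytes().translate(
        bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")
    ).decode()


def simulate_two_species_reads(
    graft_genome_length: int,
    host_genome_length: int,
    shared_fraction: float,
    n_pairs: int,
    read_length: int = 100,
    seed: int = 0,
    insert_gap: int = 50,
):
    """Simulate paired reads from a graft/host genome mixture.

    A block covering ``shared_fraction`` of each genome is copied
    verbatim into both genomes; pairs drawn entirely from that block are
    truly attributable to both species.  Returns ``(graft_genome,
    host_genome, pairs)`` where ``pairs`` is a list of
    ``(read_id, r1, r2, true_class)`` with ``true_class`` in
    {graft, host, both}.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    insert = 2 * read_length + insert_gap
    for name, length in (("graft", graft_genome_length), ("host", host_genome_length)):
        if length < insert:
            raise ValueError(f"{name} genome ({length} bp) shorter than insert ({insert} bp)")

    shared_len = round(shared_fraction * min(graft_genome_length, host_genome_length))
    shared_block = _random_sequence(rng, shared_len)
    graft = shared_block + _random_sequence(rng, graft_genome_length - shared_len)
    host = shared_block + _random_sequence(rng, host_genome_length - shared_len)

    pairs = []
    for i in range(n_pairs):
        species = "graft" if rng.random() < 0.5 else "host"
        genome = graft if species == "graft" else host
        start = int(rng.integers(0, len(genome) - insert + 1))
        r1 = genome[start : start + read_length]
        r2 = reverse_complement(genome[start + insert - read_length : start + insert])
        true_class = "both" if start + insert <= shared_len else species
        pairs.append((f"read{i:06d}", r1, r2, true_class))
    return graft, host, pairs


def write_fastq_pair(pairs, path_r1, path_r2) -> None:
    """Write 4-line FASTQ records with constant Phred+33 quality 'I'."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for read_id, r1, r2, _ in pairs:
            f1.write(f"@{read_id}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{read_id}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def write_fasta(seq: str, name: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# somatic variant cohort
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "sample", "patient", "timepoint", "chrom", "pos", "ref", "alt", "gene",
    "alt_reads", "depth", "vaf", "popaf_1000g", "popaf_kaviar",
]


def _draw_variant_keys(rng: np.random.Generator, n: int, genes: Sequence[str]):
    chroms = rng.integers(1, 23, size=n)
    positions = rng.choice(90_000_000, size=n, replace=False) + 1
    refs = rng.integers(0, 4, size=n)
    alts = (refs + rng.integers(1, 4, size=n)) % 4
    bases = "ACGT"
    keys = [
        (f"chr{c}", int(p), bases[r], bases[a])
        for c, p, r, a in zip(chroms, positions, refs, alts)
    ]
    gene_syms = rng.choice(np.asarray(genes), size=n)
    return keys, list(gene_syms)


def _passing_evidence(rng: np.random.Generator):
    vaf = float(rng.uniform(0.15, 0.6))
    alt = int(rng.integers(8, 60))
    depth = max(alt, int(round(alt / vaf)))
    return alt, depth, alt / depth, float(rng.uniform(0, 0.005)), float(rng.uniform(0, 0.005))


def _failing_evidence(rng: np.random.Generator, rule: str):
    """Evidence failing exactly one filter rule."""
    alt, depth, vaf, p1, p2 = _passing_evidence(rng)
    if rule == "support":
        alt = int(rng.integers(1, 5))
        depth = max(int(round(alt / 0.3)), alt)
        vaf = alt / depth
    elif rule == "vaf":
        vaf_t = float(rng.uniform(0.005, 0.045))
        alt = int(rng.integers(5, 10))
        depth = int(np.ceil(alt / vaf_t))
        vaf = alt / depth
    elif rule == "population":
        which = rng.random()
        hi = float(rng.uniform(0.02, 0.3))
        p1 = hi if which < 0.5 else p1
        p2 = hi if which >= 0.5 else p2
    else:  # pragma: no cover
        raise ValueError(rule)
    return alt, depth, vaf, p1, p2


def simulate_variant_cohort(
    spec: CohortSpec, decoy_fraction: float = 0.5
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit per-sample somatic variant tables with planted clonal structure.

    Per patient: ``n_variants_shared`` variants in all timepoints,
    ``n_variants_relapse_gained`` in relapse and both PDX models, and
    ``n_variants_pdx_private`` in exactly one PDX model.  A
    ``decoy_fraction`` of additional calls are planted that fail exactly
    one of the three filter rules (support / VAF / population
    frequency); the ground-truth sets contain only passing variants.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    truth = GroundTruth()
    rows = []
    n_per_patient = (
        spec.n_variants_shared + spec.n_variants_relapse_gained + spec.n_variants_pdx_private
    )
    for patient in spec.patients:
        keys, key_genes = _draw_variant_keys(rng, max(n_per_patient, 1), genes)
        shared = keys[: spec.n_variants_shared]
        gained = keys[spec.n_variants_shared : spec.n_variants_shared + spec.n_variants_relapse_gained]
        private = keys[spec.n_variants_shared + spec.n_variants_relapse_gained : n_per_patient]
        gene_of = dict(zip(keys, key_genes))
        private_home = str(rng.choice(PDX_TIMEPOINTS))

        membership: dict[str, list] = {tp: [] for tp in spec.timepoints}
        for tp in spec.timepoints:
            membership[tp].extend(shared)
            if tp in ("relapse",) + PDX_TIMEPOINTS:
                membership[tp].extend(gained)
        membership[private_home].extend(private)

        for tp in spec.timepoints:
            sample = spec.sample_id(patient, tp)
            truth.variant_sets_per_sample[sample] = set(membership[tp])
            for key in membership[tp]:
                alt, depth, vaf, p1, p2 = _passing_evidence(rng)
                rows.append(
                    (sample, patient, tp, *key, gene_of[key], alt, depth, vaf, p1, p2)
                )
            n_decoys = round(decoy_fraction * len(membership[tp]))
            if n_decoys:
                dkeys, dgenes = _draw_variant_keys(rng, n_decoys, genes)
                for key, gene in zip(dkeys, dgenes):
                    rule = ("support", "vaf", "population")[int(rng.integers(0, 3))]
                    alt, depth, vaf, p1, p2 = _failing_evidence(rng, rule)
                    rows.append((sample, patient, tp, *key, gene, alt, depth, vaf, p1, p2))
    calls = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    return calls, truth


# ---------------------------------------------------------------------------
# copy-number profiles
# ---------------------------------------------------------------------------

_ALTERED_CN = (0, 1, 4, 7, 10)  # deletion, loss, gain, amplification levels

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]


def simulate_cna_profiles(
    spec: CohortSpec,
    n_shared: int = 6,
    n_relapse_gained: int = 3,
    n_pdx_private: int = 2,
    chrom_length: int = 100_000_000,
    n_chroms: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Plant copy-number alterations mirroring the variant clonal design.

    Alterations are non-overlapping segments with total copy number in
    {0, 1, 4, 7, 10} and lengths straddling the 5 Mb focality boundary;
    the rest of the genome is emitted as neutral (cn=2) filler.  Returns
    (segments, gene_intervals, truth) where truth holds per-sample
    (gene, category) alteration sets.
    """
    from . import cna as _cna  # category rule lives in the cna module

    rng = np.random.default_rng(spec.seed + 1)
    # tile genes along the genome, 1 Mb apart, 100 kb long
    gene_rows = []
    gi = 0
    for c in range(n_chroms):
        for start in range(1, chrom_length - 1_000_000, 1_000_000):
            gene_rows.append((f"G{gi:04d}", f"chr{c + 1}", start, start + 100_000))
            gi += 1
            if gi >= spec.n_genes:
                break
        if gi >= spec.n_genes:
            break
    gene_intervals = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])

    truth = GroundTruth()
    seg_rows = []
    n_total = n_shared + n_relapse_gained + n_pdx_private
    for patient in spec.patients:
        # non-overlapping alteration slots: one per 10 Mb window
        slots = rng.choice(n_chroms * (chrom_length // 10_000_000), size=n_total, replace=False)
        alts = []
        for slot in slots:
            chrom = f"chr{slot // (chrom_length // 10_000_000) + 1}"
            wstart = int(slot % (chrom_length // 10_000_000)) * 10_000_000 + 1
            cn = int(rng.choice(_ALTERED_CN))
            length = int(rng.choice([1_000_000, 4_000_000, 8_000_000]))
            alts.append((chrom, wstart, wstart + length, cn))
        shared, gained, private = (
            alts[:n_shared],
            alts[n_shared : n_shared + n_relapse_gained],
            alts[n_shared + n_relapse_gained :],
        )
        private_home = str(rng.choice(PDX_TIMEPOINTS))
        for tp in spec.timepoints:
            sample = spec.sample_id(patient, tp)
            segs = list(shared)
            if tp in ("relapse",) + PDX_TIMEPOINTS:
                segs += gained
            if tp == private_home:
                segs += private
            for chrom, start, end, cn in sorted(segs):
                seg_rows.append((sample, chrom, start, end, cn))
            # neutral filler for one chromosome arm so profiles look SEG-like
            seg_rows.append((sample, f"chr{n_chroms}", 95_000_001, chrom_length, 2))
            gene_calls = set()
            for chrom, start, end, cn in segs:
                cat = _cna.classify_segment(cn, end - start)
                if cat == "neutral":
                    continue
                hit = gene_intervals[
                    (gene_intervals.chrom == chrom)
                    & (gene_intervals.start < end)
                    & (gene_intervals.end > start)
                ]
                gene_calls.update((g, cat) for g in hit.gene)
            truth.cna_sets_per_sample[sample] = gene_calls
    segments = pd.DataFrame(seg_rows, columns=_SEG_COLUMNS)
    return segments, gene_intervals, truth


# ---------------------------------------------------------------------------
# fusion calls
# ---------------------------------------------------------------------------

_FUSION_COLUMNS = [
    "tool", "sample", "gene5", "gene3",
    "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3", "junction_reads",
]


def simulate_fusion_calls(
    spec: CohortSpec,
    n_fusions_per_patient: int = 8,
    seed_offset: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Emit per-tool fusion tables plus a junction-read evidence table.

    Each planted fusion is reported by a random subset of the
    ``fusion_tool_count`` callers and assigned a junction-read count in
    the validation evidence; survivors of the consensus (>=3 distinct
    tools) AND validation (>=1 junction read) rules are recorded in
    ``truth.true_fusion_survivors`` as (sample, gene5, gene3) triples.
    Fusions conserved across timepoints reuse the same gene pair.
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    tools = list(FUSION_TOOLS[: spec.fusion_tool_count])
    truth = GroundTruth()
    call_rows, ev_rows = [], []
    fid = 0
    for patient in spec.patients:
        for _ in range(n_fusions_per_patient):
            g5, g3 = f"F{fid:03d}A", f"F{fid:03d}B"
            fid += 1
            # longitudinal presence pattern
            pattern = rng.choice(
                ["diagnosis_conserved", "relapse_conserved", "single"], p=[0.35, 0.25, 0.4]
            )
            if pattern == "diagnosis_conserved":
                present = ["diagnosis", "relapse", str(rng.choice(PDX_TIMEPOINTS))]
            elif pattern == "relapse_conserved":
                present = ["relapse", str(rng.choice(PDX_TIMEPOINTS))]
            else:
                present = [str(rng.choice(spec.timepoints))]
            n_tools = int(rng.integers(1, len(tools) + 1))
            chosen = list(rng.choice(tools, size=n_tools, replace=False))
            jr = int(rng.integers(0, 2)) * int(rng.integers(1, 30))
            bp5 = (f"chr{rng.integers(1, 23)}", int(rng.integers(1, 10**8)), "+")
            bp3 = (f"chr{rng.integers(1, 23)}", int(rng.integers(1, 10**8)), "-")
            for tp in present:
                sample = spec.sample_id(patient, tp)
                for tool in chosen:
                    call_rows.append(
                        (tool, sample, g5, g3, bp5[0], bp5[1] + int(rng.integers(-5, 6)),
                         bp5[2], bp3[0], bp3[1] + int(rng.integers(-5, 6)), bp3[2],
                         int(rng.integers(1, 20)))
                    )
                ev_rows.append((sample, g5, g3, jr))
                if n_tools >= 3 and jr >= 1:
                    truth.true_fusion_survivors.add((sample, g5, g3))
                    truth.fusion_presence.setdefault((patient, g5, g3), set()).add(tp)
    calls = pd.DataFrame(call_rows, columns=_FUSION_COLUMNS)
    evidence = pd.DataFrame(ev_rows, columns=["sample", "gene5", "gene3", "junction_reads"])
    return calls, evidence, truth


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.clip(mean, 1e-8, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression_cohort(
    spec: CohortSpec,
    dispersion: float = 0.2,
    species_amplitude: float = 1.0,
    bio_amplitudes: Sequence[float] = (1.0, 0.8),
    me_program_amplitude: float = 1.5,
    me_leakage: float = 0.0,
):
    """Low-rank negative-binomial expression cohort with planted structure.

    Human samples = patient tumors (diagnosis, relapse) plus the human
    fraction of each PDX; mouse samples = the PDX mouse fraction
    (microenvironment).  Planted features:

    * ``n_me_genes`` microenvironment genes: mean 50-500 counts in
      patient samples, hard zero (or ``me_leakage`` mean) in the PDX
      human fraction, with their mouse orthologs expressed in the mouse
      fraction following a per-patient ME program shared across species;
    * one latent factor whose sample score depends only on the
      patient-vs-PDX split (the species-separation factor);
    * biological factors loading across all samples, each contributing
      more than 5% of variance under the default amplitudes.

    Returns ``(counts_human, counts_mouse, sample_meta, ortholog_map,
    truth)``; count matrices are gene x sample DataFrames.
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    mouse_genes = [f"Gm{i:04d}" for i in range(spec.n_genes)]
    me_idx = np.sort(rng.choice(spec.n_genes, size=spec.n_me_genes, replace=False))
    me_mask = np.zeros(spec.n_genes, dtype=bool)
    me_mask[me_idx] = True

    human_samples, meta_rows = [], []
    for patient in spec.patients:
        for tp in PATIENT_TIMEPOINTS:
            s = spec.sample_id(patient, tp)
            human_samples.append(s)
            meta_rows.append((s, "human", "patient", patient, tp))
        for tp in PDX_TIMEPOINTS:
            s = spec.sample_id(patient, tp)
            human_samples.append(s)
            meta_rows.append((s, "human", "pdx_human", patient, tp))
    mouse_samples = [
        f"{spec.sample_id(p, tp)}_mouse" for p in spec.patients for tp in PDX_TIMEPOINTS
    ]
    for p in spec.patients:
        for tp in PDX_TIMEPOINTS:
            meta_rows.append((f"{spec.sample_id(p, tp)}_mouse", "mouse", "pdx_mouse", p, tp))
    sample_meta = pd.DataFrame(
        meta_rows, columns=["sample", "species", "fraction", "patient", "timepoint"]
    )

    n_h = len(human_samples)
    base_log2 = rng.normal(5.0, 1.5, size=spec.n_genes)  # ~32-count median baseline
    is_pdx = np.array(
        [sample_meta.set_index("sample").loc[s, "fraction"] == "pdx_human" for s in human_samples]
    )
    species_scores = np.where(is_pdx, -1.0, 1.0)
    n_factors = 1 + len(bio_amplitudes)
    factor_scores = np.empty((n_h, n_factors))
    factor_scores[:, 0] = species_scores
    # biology factors load across ALL samples: center within each species
    # group so they are balanced (orthogonal to the species contrast),
    # then orthogonalize among themselves and standardize
    for j in range(len(bio_amplitudes)):
        z = rng.normal(0, 1, size=n_h)
        for prev in range(j + 1):
            q = factor_scores[:, prev]
            z = z - q * (z @ q) / (q @ q)
        factor_scores[:, 1 + j] = (z - z.mean()) / z.std()
    loadings = rng.normal(0, 1, size=(spec.n_genes, n_factors))
    # the species shift acts on expressed genes: a gene silent in the PDX
    # human fraction but high in patients is by definition an ME gene, so
    # the species factor must not manufacture such genes outside the
    # planted ME set
    loadings[base_log2 < 4.0, 0] = 0.0
    amps = np.array([species_amplitude, *bio_amplitudes])

    log2_mu = base_log2[:, None] + (loadings * amps) @ factor_scores.T
    mu = 2.0 ** np.clip(log2_mu, -4, 16)

    # plant ME genes: strong in patient columns, (near-)absent in pdx_human
    me_means = rng.uniform(50, 500, size=spec.n_me_genes)
    patient_u = {p: rng.normal(0, 1, size=spec.n_me_genes) for p in spec.patients}
    meta_ix = sample_meta.set_index("sample")
    for col, s in enumerate(human_samples):
        frac = meta_ix.loc[s, "fraction"]
        pat = meta_ix.loc[s, "patient"]
        if frac == "patient":
            mu[me_idx, col] = me_means * 2.0 ** (me_program_amplitude * patient_u[pat])
        else:
            mu[me_idx, col] = me_leakage

    counts_h = _nb_sample(rng, mu, dispersion)
    if me_leakage == 0.0:
        counts_h[np.ix_(me_idx, np.where(is_pdx)[0])] = 0
    counts_human = pd.DataFrame(counts_h, index=genes, columns=human_samples)

    # mouse fraction: orthologs of ME genes carry the same per-patient program
    n_m = len(mouse_samples)
    mouse_base = rng.normal(3.0, 1.0, size=spec.n_genes)
    mu_m = 2.0 ** np.clip(mouse_base[:, None] + rng.normal(0, 0.3, size=(spec.n_genes, n_m)), -4, 16)
    for col, s in enumerate(mouse_samples):
        pat = meta_ix.loc[s, "patient"]
        mu_m[me_idx, col] = me_means * 2.0 ** (me_program_amplitude * patient_u[pat])
    counts_m = _nb_sample(rng, mu_m, dispersion)
    counts_mouse = pd.DataFrame(counts_m, index=mouse_genes, columns=mouse_samples)

    ortholog_map = pd.DataFrame({"human_gene": genes, "mouse_gene": mouse_genes})

    truth = GroundTruth(
        me_gene_ids={genes[i] for i in me_idx},
        species_factor_index=0,
        factor_scores=pd.DataFrame(
            factor_scores,
            index=human_samples,
            columns=[f"factor{j}" for j in range(n_factors)],
        ),
    )
    return counts_human, counts_mouse, sample_meta, ortholog_map, truth


# ---------------------------------------------------------------------------
# protein abundance matrix
# ---------------------------------------------------------------------------

def simulate_protein_matrix(
    n_proteins: int = 300,
    n_samples: int = 8,
    rank: int = 2,
    missing_rate: float = 0.2,
    high_missing_fraction: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low-rank log-abundance matrix with MCAR missing values.

    Most proteins receive missingness at ``missing_rate`` (below the
    34% imputability filter); a ``high_missing_fraction`` of proteins
    get >50% missing cells to exercise the filter.  Returns
    (observed_with_nans, complete_truth).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 1, size=(n_proteins, rank))
    v = rng.normal(0, 1, size=(rank, n_samples))
    full = u @ v + rng.normal(0, noise_sd, size=(n_proteins, n_samples)) + 20.0
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    complete = pd.DataFrame(full, index=proteins, columns=samples)
    observed = complete.copy()
    mask = rng.random(size=full.shape) < missing_rate
    n_high = round(high_missing_fraction * n_proteins)
    high_rows = rng.choice(n_proteins, size=n_high, replace=False)
    mask[high_rows] = rng.random(size=(n_high, n_samples)) < 0.6
    # keep at least one observed cell per row
    for i in range(n_proteins):
        if mask[i].all():
            mask[i, int(rng.integers(0, n_samples))] = False
    observed.values[mask] = np.nan
    return observed, complete


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    v0: float,
    td_days: float,
    noise_cv: float,
    t_grid: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential tumor growth V(t) = v0 * 2**(t/td) with lognormal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    measurement error (volumes stay positive).
    """
    if v0 <= 0 or td_days <= 0:
        raise ValueError("v0 and td_days must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float)
    v = v0 * 2.0 ** (t / td_days)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        v = v * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=t.shape)
    return pd.DataFrame({"day": t, "volume_mm3": v})
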