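"""Five-class graft/host read partitioning with a chimeric k-mer index.

Xenograft sequencing mixes reads from the implanted human tumor (graft)
and the mouse carrying it (host).  A chimeric index built from both
reference genomes stores every canonical k-mer in one of three disjoint
sets — graft-only, host-only, shared — and each read (pair) is assigned
one of five classes: graft, host, both (only shared k-mers), neither
(no k-mer found) or ambiguous (evidence for both species).

The decision rule is transparent evidence counting: a read is *graft*
iff it matches >=1 graft-only k-mer and no host-only k-mer, *host*
symmetrically, *ambiguous* if it matches both species-specific sets,
*both* if it only matches shared k-mers, *neither* otherwise.  Mates of
a pair are never split: mate classes combine through a fixed table in
which any graft/host conflict is ambiguous, a species class dominates
both/neither, and both dominates neither.

The index is in-memory and intended for genomes up to a few hundred kb;
whole-genome scale indexing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .synthetic import reverse_complement

logger = logging.getLogger(__name__)

CLASSES = ("graft", "host", "both", "neither", "ambiguous")


@dataclass(frozen=True)
class ChimericKmerIndex:
    """Disjoint canonical k-mer sets for the graft and host genomes."""

    k: int
    graft_only: frozenset[str]
    host_only: frozenset[str]
    shared: frozenset[str]


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    klass: str
    n_graft_kmers: int
    n_host_kmers: int
    n_shared_kmers: int
    n_absent_kmers: int


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _kmers_of(seq: str, k: int):
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        yield canonical_kmer(km)


def _fasta_kmers(path, k: int) -> set[str]:
    kmers: set[str] = set()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        kmers.update(_kmers_of(str(record.seq), k))
    if n_records == 0:
        raise ValueError(f"no sequences in {path}")
    return kmers


def build_index(graft_fasta, host_fasta, k: int = 21) -> ChimericKmerIndex:
    """Build the chimeric index from two reference FASTA files.

    ``k`` must be odd (so no k-mer is its own reverse complement) and in
    [11, 31].  k-mers containing N are skipped; a k-mer present in both
    genomes is stored only in the shared set.
    """
    if not 11 <= k <= 31 or k % 2 == 0:
        raise ValueError("k must be odd and in [11, 31]")
    graft = _fasta_kmers(graft_fasta, k)
    host = _fasta_kmers(host_fasta, k)
    shared = graft & host
    return ChimericKmerIndex(
        k=k,
        graft_only=frozenset(graft - shared),
        host_only=frozenset(host - shared),
        shared=frozenset(shared),
    )


def classify_read(read: str, index: ChimericKmerIndex, read_id: str = "") -> ReadClassification:
    """Classify a single read by counting matches in the three k-mer sets."""
    n_g = n_h = n_s = n_a = 0
    if len(read) < index.k:
        logger.warning("read %s shorter than k=%d -> neither", read_id, index.k)
        return ReadClassification(read_id, "neither", 0, 0, 0, 0)
    for km in _kmers_of(read, index.k):
        if km in index.graft_only:
            n_g += 1
        elif km in index.host_only:
            n_h += 1
        elif km in index.shared:
            n_s += 1
        else:
            n_a += 1
    if n_g and n_h:
        klass = "ambiguous"
    elif n_g:
        klass = "graft"
    elif n_h:
        klass = "host"
    elif n_s:
        klass = "both"
    else:
        klass = "neither"
    return ReadClassification(read_id, klass, n_g, n_h, n_s, n_a)


#: pair-resolution: identical classes persist; graft/host conflict -> ambiguous;
#: a species class dominates both/neither; both dominates neither;
#: ambiguous absorbs everything.
def combine_mate_classes(c1: str, c2: str) -> str:
    if c1 == c2:
        return c1
    pair = {c1, c2}
    if "ambiguous" in pair:
        return "ambiguous"
    if pair == {"graft", "host"}:
        return "ambiguous"
    for species in ("graft", "host"):
        if species in pair:
            return species
    return "both"  # remaining case: {both, neither}


def _read_fastq(path):
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]


def classify_pairs(fastq_r1, fastq_r2, index: ChimericKmerIndex, out_prefix=None):
    """Partition read pairs into the five classes.

    Returns ``(assignments, summary)`` where assignments maps read id to
    class and summary is a DataFrame (class, n_pairs, fraction).  When
    ``out_prefix`` is given, writes ``<prefix>_<class>_{1,2}.fastq``
    files (4-line records) plus the summary TSV.
    """
    import pandas as pd

    r1 = _read_fastq(fastq_r1)
    r2 = _read_fastq(fastq_r2)
    if len(r1) != len(r2):
        raise ValueError(f"R1 has {len(r1)} reads but R2 has {len(r2)}")
    assignments: dict[str, str] = {}
    buckets = {c: [] for c in CLASSES}
    for (id1, s1), (id2, s2) in zip(r1, r2):
        c1 = classify_read(s1, index, id1).klass
        c2 = classify_read(s2, index, id2).klass
        klass = combine_mate_classes(c1, c2)
        pair_id = id1.rsplit("/", 1)[0]
        assignments[pair_id] = klass
        buckets[klass].append((id1, s1, id2, s2))
    n = len(r1)
    summary = pd.DataFrame(
        {
            "class": CLASSES,
            "n_pairs": [len(buckets[c]) for c in CLASSES],
            "fraction": [len(buckets[c]) / n if n else 0.0 for c in CLASSES],
        }
    )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        for klass in CLASSES:
            with open(f"{prefix}_{klass}_1.fastq", "w") as f1, open(
                f"{prefix}_{klass}_2.fastq", "w"
            ) as f2:
                for id1, s1, id2, s2 in buckets[klass]:
                    f1.write(f"@{id1}\n{s1}\n+\n{'I' * len(s1)}\n")
                    f2.write(f"@{id2}\n{s2}\n+\n{'I' * len(s2)}\n")
        summary.to_csv(f"{prefix}_summary.tsv", sep="\t", index=False)
    return assignments, summary
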