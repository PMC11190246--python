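"""K-mer count featurization of DNA sequences.

Sequences become fixed-length integer vectors: each column is one K-mer from
a vocabulary fitted on the training corpus (sorted union of observed K-mers,
K = 6 by default), each entry the number of sliding-window occurrences.
Prediction-time sequences are counted against the training vocabulary only;
out-of-vocabulary K-mers are dropped (and tallied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AMBIGUOUS = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered (lexicographic) vocabulary of K-mers defining feature columns."""

    K: int
    kmers: tuple[str, ...]
    index: dict[str, int] = field(compare=False, default_factory=dict)

    @staticmethod
    def from_kmers(K: int, kmers: Iterable[str]) -> "KmerVocabulary":
        ordered = tuple(sorted(set(kmers)))
        if any(len(k) != K for k in ordered):
            raise ValueError(f"all vocabulary entries must have length {K}")
        return KmerVocabulary(K, ordered, {k: i for i, k in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class KmerFeatureTable:
    """Per-sequence K-mer count matrix plus row ids and dropped-K-mer tallies."""

    vocabulary: KmerVocabulary
    counts: np.ndarray  # (n_sequences, n_kmers) non-negative ints
    ids: list[str]
    dropped: np.ndarray  # per-row count of out-of-vocabulary k-mers


def kmerize(seq: str, K: int) -> list[str]:
    """All length-K windows of ``seq`` at stride 1 (L-K+1 of them; [] if L<K)."""
    if K <= 0:
        raise ValueError(f"K must be >= 1, got {K}")
    seq = seq.upper()
    return [seq[i : i + K] for i in range(len(seq) - K + 1)]


def build_vocabulary(
    seqs: Iterable[str], K: int = 6, drop_ambiguous: bool = False
) -> KmerVocabulary:
    """Fit the vocabulary: sorted union of K-mers observed in the corpus.

    ``drop_ambiguous`` removes K-mers containing IUPAC ambiguity codes;
    by default they are kept as literal tokens, as a plain token counter would.
    """
    seen: set[str] = set()
    any_long_enough = False
    for s in seqs:
        kmers = kmerize(s, K)
        if kmers:
            any_long_enough = True
        seen.update(kmers)
    if not any_long_enough:
        raise ValueError(f"no sequence of length >= K={K} in corpus")
    if drop_ambiguous:
        seen = {k for k in seen if not (set(k) & AMBIGUOUS)}
    return KmerVocabulary.from_kmers(K, seen)


def count_vector(seq: str, vocabulary: KmerVocabulary) -> tuple[np.ndarray, int]:
    """Count vocabulary K-mers in one sequence; returns (vector, n_dropped)."""
    vec = np.zeros(len(vocabulary), dtype=np.int64)
    dropped = 0
    idx = vocabulary.index
    for kmer in kmerize(seq, vocabulary.K):
        j = idx.get(kmer)
        if j is None:
            dropped += 1
        else:
            vec[j] += 1
    return vec, dropped


def count_matrix(
    seqs: Sequence[str],
    ids: Sequence[str],
    vocabulary: KmerVocabulary,
) -> KmerFeatureTable:
    counts = np.zeros((len(seqs), len(vocabulary)), dtype=np.int64)
    dropped = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        counts[i], dropped[i] = count_vector(s, vocabulary)
    return KmerFeatureTable(vocabulary, counts, list(ids), dropped)


def featurize(
    seqs: Sequence[str], ids: Sequence[str], K: int = 6, drop_ambiguous: bool = False
) -> KmerFeatureTable:
    """Fit a vocabulary on ``seqs`` and count them against it."""
    vocab = build_vocabulary(seqs, K, drop_ambiguous)
    return count_matrix(seqs, ids, vocab)


def save_vocabulary(vocabulary: KmerVocabulary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#K={vocabulary.K}\n")
        for k in vocabulary.kmers:
            fh.write(k + "\n")


def load_vocabulary(path) -> KmerVocabulary:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#K="):
            raise ValueError(f"{path}: missing #K= header")
        K = int(header[3:])
        kmers = [line.strip() for line in fh if line.strip()]
    return KmerVocabulary.from_kmers(K, kmers)
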