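"""Reading, orienting and primer-trimming 16S rRNA gene sequences.

16S databases mix (+)- and (-)-strand entries. Orientation is decided by
locating a short conserved template (conventionally the first 50 bp of the
E. coli 16S gene) on either strand with a seed-and-extend local aligner and a
Karlin-Altschul E-value; minus-strand records are reverse complemented and
unrecognized records dropped. Hypervariable subregions (V1-V2 ... V7-V9) are
then cut out between degenerate primer sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

REGIONS = ("full-length", "V1-V2", "V1-V3", "V3-V4", "V4", "V4-V5", "V6-V8", "V7-V9")


class SequenceError(ValueError):
    """Raised for malformed sequences, primers or FASTA records."""


@dataclass
class SeqRecord:
    """A 16S sequence with an optional strand-orientation label."""

    id: str
    seq: str
    orientation: str = "unknown"  # plus | minus | unrecognized | unknown

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - set(IUPAC_SETS)
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse degenerate primers delimiting a region.

    Both primers are written 5'->3' on their own strand, the usual convention:
    the reverse primer anneals to the (+) strand as its reverse complement.
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.name not in REGIONS:
            raise SequenceError(f"unknown region label {self.name!r}; expected one of {REGIONS}")
        for p in (self.forward, self.reverse):
            bad = set(p.upper()) - set(IUPAC_SETS)
            if bad:
                raise SequenceError(f"primer {p!r}: non-IUPAC characters {sorted(bad)}")
        if self.max_mismatch < 0:
            raise SequenceError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class OrientationResult:
    label: str  # plus | minus | unrecognized
    best_score: float
    evalue: float


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, order preserved)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise SequenceError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (M<->K, R<->Y, N<->N ...)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise SequenceError(f"non-IUPAC character {exc.args[0]!r}") from None


@dataclass(frozen=True)
class AlignerConfig:
    """Seed-and-extend scoring for orientation detection.

    Ungapped extension with BLASTN-like defaults; E = K*m*n*exp(-lambda*S).
    """

    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    lam: float = 1.28
    k: float = 0.46
    # maps "template hit on forward strand" -> plus; flip if a corpus uses the
    # opposite labeling convention
    invert_strands: bool = False


def _best_ungapped_score(seq: str, template: str, cfg: AlignerConfig) -> int:
    """Best ungapped local-alignment score over exact word seeds."""
    w = cfg.word_size
    words: dict[str, list[int]] = {}
    for j in range(len(template) - w + 1):
        words.setdefault(template[j : j + w], []).append(j)
    best = 0
    for i in range(len(seq) - w + 1):
        for j in words.get(seq[i : i + w], ()):
            score = cfg.match * w
            # extend right
            cur = score
            x, y = i + w, j + w
            right = 0
            while x < len(seq) and y < len(template):
                cur += cfg.match if seq[x] == template[y] else cfg.mismatch
                if cur > score + right:
                    right = cur - score
                if cur < score + right - 20:  # X-drop
                    break
                x += 1
                y += 1
            # extend left
            cur = 0
            x, y = i - 1, j - 1
            left = 0
            while x >= 0 and y >= 0:
                cur += cfg.match if seq[x] == template[y] else cfg.mismatch
                if cur > left:
                    left = cur
                if cur < left - 20:
                    break
                x -= 1
                y -= 1
            total = score + right + left
            if total > best:
                best = total
    return best


def detect_orientation(
    record: SeqRecord,
    template: str,
    evalue_threshold: float = 0.01,
    config: AlignerConfig | None = None,
) -> OrientationResult:
    """Decide which strand of ``record`` carries the conserved template.

    The template is aligned against the record and against its reverse
    complement; the better-scoring strand wins if its E-value clears the
    threshold, otherwise the record is labeled unrecognized.
    """
    cfg = config or AlignerConfig()
    template = template.upper()
    if len(template) < cfg.word_size:
        raise SequenceError(
            f"template length {len(template)} < word size {cfg.word_size}"
        )
    fwd = _best_ungapped_score(record.seq, template, cfg)
    rev = _best_ungapped_score(reverse_complement(record.seq), template, cfg)
    score = max(fwd, rev)
    m, n = len(record.seq), len(template)
    evalue = cfg.k * m * n * math.exp(-cfg.lam * score)
    if evalue >= evalue_threshold:
        return OrientationResult("unrecognized", float(score), evalue)
    label = "plus" if fwd >= rev else "minus"
    if cfg.invert_strands:
        label = "minus" if label == "plus" else "plus"
    return OrientationResult(label, float(score), evalue)


def orient_all(
    records: Iterable[SeqRecord],
    template: str,
    evalue_threshold: float = 0.01,
    config: AlignerConfig | None = None,
    rejects: Optional[list] = None,
) -> tuple[list[SeqRecord], int]:
    """Flip minus-strand records to plus; drop and count unrecognized ones.

    ``rejects``, if given, collects (id, reason) tuples for a rejects report.
    """
    out: list[SeqRecord] = []
    n_excluded = 0
    for rec in records:
        res = detect_orientation(rec, template, evalue_threshold, config)
        if res.label == "unrecognized":
            n_excluded += 1
            if rejects is not None:
                rejects.append((rec.id, "unrecognized_orientation"))
            continue
        if res.label == "minus":
            out.append(replace(rec, seq=reverse_complement(rec.seq), orientation="plus"))
        else:
            out.append(replace(rec, orientation="plus"))
    return out, n_excluded


def _iupac_match(primer_base: str, seq_base: str) -> bool:
    return bool(IUPAC_SETS[primer_base] & IUPAC_SETS[seq_base])


def _mismatches(seq: str, primer: str, offset: int) -> int:
    return sum(
        0 if _iupac_match(p, seq[offset + i]) else 1 for i, p in enumerate(primer)
    )


def find_primer_site(
    seq: str,
    primer: str,
    max_mismatch: int = 0,
    search_strand: str = "forward",
) -> Optional[tuple[int, int]]:
    """Locate a degenerate primer in ``seq``; 0-based half-open interval.

    A primer base matches a sequence base iff their IUPAC sets intersect.
    The lowest-mismatch site wins; ties break leftmost for forward primers
    and rightmost for reverse primers (``search_strand='reverse'`` scans for
    the reverse complement of the primer).
    """
    seq = seq.upper()
    primer = primer.upper()
    if search_strand == "reverse":
        primer = reverse_complement(primer)
    L, P = len(seq), len(primer)
    if P > L:
        return None
    best_mm = max_mismatch + 1
    best_at = None
    offsets = range(L - P + 1) if search_strand == "forward" else range(L - P, -1, -1)
    for off in offsets:
        mm = _mismatches(seq, primer, off)
        if mm < best_mm:
            best_mm = mm
            best_at = off
            if mm == 0:
                break
    if best_at is None:
        return None
    return (best_at, best_at + P)


def extract_region(
    record: SeqRecord,
    primer_pair: PrimerPair,
    include_primers: bool = False,
) -> Optional[SeqRecord]:
    """Cut the subregion delimited by a primer pair from a plus-strand record.

    Returns the insert between the two primer annealing sites (primers
    excluded unless ``include_primers``); None if either primer is absent or
    the reverse site is not downstream of the forward site.
    """
    fwd = find_primer_site(record.seq, primer_pair.forward, primer_pair.max_mismatch, "forward")
    if fwd is None:
        return None
    # the reverse primer anneals downstream; search only past the forward site
    downstream = record.seq[fwd[1]:]
    rev = find_primer_site(downstream, primer_pair.reverse, primer_pair.max_mismatch, "reverse")
    if rev is None:
        return None
    rev = (rev[0] + fwd[1], rev[1] + fwd[1])
    if include_primers:
        start, end = fwd[0], rev[1]
    else:
        start, end = fwd[1], rev[0]
    if end <= start:
        return None
    return replace(record, seq=record.seq[start:end])
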