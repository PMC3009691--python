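"""Pairwise similarity: low-complexity masking, hit filtering, symmetrification.

The clustering distance between two enzymes is the E-value of their pairwise
local alignment.  Hits come either from the built-in aligner
(:mod:`enzpat.align`) or from external BLAST tabular output; in both cases
they pass through the same filters: alignments shorter than 50 columns or
with an E-value above 1e-3 are discarded, and the two directed E-values of
a pair are symmetrified by keeping the higher one (the less similar
direction), so multidomain proteins cannot drag unrelated single-domain
families together.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, TextIO

from .sequence_db import SequenceRecord

log = logging.getLogger(__name__)

MIN_ALIGNED_COLS = 50
MAX_EVALUE = 1e-3

#: External BLAST may print an E-value of exactly 0; clamp so the max() and
#: ordering used in clustering stay well-defined.
EVALUE_FLOOR = 1e-180


@dataclass(frozen=True)
class PairwiseHit:
    """One directed local-alignment hit (1-based inclusive coordinates)."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aligned_cols: int
    evalue: float

    def __post_init__(self) -> None:
        if not (self.q_start <= self.q_end and self.t_start <= self.t_end):
            raise ValueError(f"inverted coordinates in hit {self}")
        if self.aligned_cols < 1:
            raise ValueError("aligned_cols must be >= 1")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive (clamp zeros upstream)")


@dataclass(frozen=True)
class DistanceEntry:
    """Symmetric clustering distance for an unordered pair of records."""

    id_a: str
    id_b: str
    distance: float

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("DistanceEntry ids must satisfy id_a < id_b")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))


class AlignerContract(Protocol):
    """Pluggable similarity/alignment provider.

    Must be deterministic for a fixed configuration.  ``pairwise_hits``
    yields directed hits between the given records (no self hits);
    ``msa`` aligns a list of sequences into equal-length gapped rows.
    """

    def pairwise_hits(
        self, records: Sequence[tuple[str, str]]
    ) -> list[PairwiseHit]: ...

    def msa(self, sequences: Sequence[str]) -> list[str]: ...


# ---------------------------------------------------------------------------
# Low-complexity masking


def mask_low_complexity(
    sequence: str, window: int | None = 12, threshold: float = 2.2
) -> str:
    """Replace low-complexity runs with ``X``.

    A sliding window of ``window`` residues is masked entirely whenever its
    Shannon entropy (bits over residue frequencies) falls below
    ``threshold``.  This is a simplified stand-in for SEG-style filters; a
    pipeline can instead supply externally pre-masked sequences, in which
    case this step is skipped (``window=None`` is the identity).  Masking
    affects the similarity search only, never the stored sequence.
    """
    if not window or len(sequence) < window:
        return sequence
    masked = list(sequence)
    to_mask = [False] * len(sequence)
    counts = Counter(sequence[:window])

    def entropy(counter: Counter) -> float:
        total = sum(counter.values())
        return -sum(
            (c / total) * math.log2(c / total) for c in counter.values() if c
        )

    for start in range(len(sequence) - window + 1):
        if start > 0:
            counts[sequence[start - 1]] -= 1
            if counts[sequence[start - 1]] == 0:
                del counts[sequence[start - 1]]
            counts[sequence[start + window - 1]] += 1
        if entropy(counts) < threshold:
            for i in range(start, start + window):
                to_mask[i] = True
    for i, flag in enumerate(to_mask):
        if flag:
            masked[i] = "X"
    return "".join(masked)


# ---------------------------------------------------------------------------
# All-vs-all search


def all_vs_all(
    records: Sequence[SequenceRecord],
    aligner: AlignerContract,
    mask: bool = True,
    window: int | None = 12,
    threshold: float = 2.2,
) -> list[PairwiseHit]:
    """Directed hits between all pairs of (non-redundant) enzyme records.

    Sequences are low-complexity masked before the search unless ``mask``
    is false.  Self hits are discarded by contract of the aligner.
    """
    pairs = []
    for rec in records:
        seq = (
            mask_low_complexity(rec.sequence, window, threshold)
            if mask
            else rec.sequence
        )
        pairs.append((rec.id, seq))
    return aligner.pairwise_hits(pairs)


def filter_hits(
    hits: Iterable[PairwiseHit],
    min_aligned_cols: int = MIN_ALIGNED_COLS,
    max_evalue: float = MAX_EVALUE,
) -> list[PairwiseHit]:
    """Keep hits covering >= ``min_aligned_cols`` columns with E-value
    <= ``max_evalue`` (boundary values retained).  Idempotent."""
    return [
        h
        for h in hits
        if h.aligned_cols >= min_aligned_cols and h.evalue <= max_evalue
    ]


def symmetrify(hits: Iterable[PairwiseHit]) -> list[DistanceEntry]:
    """Reduce directed hits to one symmetric distance per unordered pair.

    Multiple hits in one direction collapse to that direction's minimum
    (best) E-value first; then the pair's distance is the maximum of the
    two directed E-values.  A pair with a hit in only one direction gets
    no entry: the missing reciprocal hit would have had an E-value above
    the reporting threshold, so max() would exclude the pair anyway.
    """
    directed: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query_id == h.target_id:
            continue
        key = (h.query_id, h.target_id)
        if key not in directed or h.evalue < directed[key]:
            directed[key] = h.evalue
    entries: list[DistanceEntry] = []
    for (q, t), ev in sorted(directed.items()):
        if q < t:
            reciprocal = directed.get((t, q))
            if reciprocal is not None:
                entries.append(DistanceEntry(q, t, max(ev, reciprocal)))
    return entries


# ---------------------------------------------------------------------------
# External BLAST import / TSV persistence


def read_blast_tabular(stream: TextIO) -> list[PairwiseHit]:
    """Map BLAST outfmt-6 rows onto hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates on the minus strand
    (sstart > send, possible for translated searches) are normalized;
    E-values of 0 are clamped to ``EVALUE_FLOOR``.
    """
    hits: list[PairwiseHit] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        qseqid, sseqid = cols[0], cols[1]
        length = int(cols[3])
        qstart, qend = int(cols[6]), int(cols[7])
        sstart, send = int(cols[8]), int(cols[9])
        if sstart > send:
            sstart, send = send, sstart
        evalue = float(cols[10])
        if evalue <= 0:
            evalue = EVALUE_FLOOR
        hits.append(
            PairwiseHit(
                query_id=qseqid,
                target_id=sseqid,
                q_start=qstart,
                q_end=qend,
                t_start=sstart,
                t_end=send,
                aligned_cols=length,
                evalue=evalue,
            )
        )
    return hits


def write_distances(entries: Sequence[DistanceEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tevalue\n")
        for e in sorted(entries, key=lambda e: (e.id_a, e.id_b)):
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.distance:.6g}\n")


def read_distances(path: str | Path) -> list[DistanceEntry]:
    entries: list[DistanceEntry] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            id_a, id_b, ev = line.rstrip("\n").split("\t")
            entries.append(DistanceEntry(id_a, id_b, float(ev)))
    return entries
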