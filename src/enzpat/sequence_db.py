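"""Annotated protein database handling.

Parses Swiss-Prot-style flat files (or FASTA plus a sidecar annotation
table), sorts entries into the three working groups -- enzymes, putative
proteins, and proteins without enzymatic activity -- removes redundant
entries, and applies IUBMB EC-number transfer/deletion updates.

Group semantics
---------------
ENZYME      entry carries >=1 EC number, no "putative"-style keyword, and a
            sequence length within [100, 7000].  Only this group enters the
            similarity/clustering pipeline.
PUTATIVE    description contains a keyword such as "putative",
            "hypothetical" or "fragment" -- function considered unknown.
            EC-bearing entries outside the length bounds are also routed
            here so they still contribute neutral evidence downstream.
NON_ENZYME  no EC number and no keyword.

The latter two groups are used only when verifying pattern specificity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from .ec import ECNumber, ECParseError, extract_ec_tokens, format_ec_set, parse_ec_set

log = logging.getLogger(__name__)

#: Case-insensitive description keywords that route an entry to PUTATIVE.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "putative",
    "hypothetical",
    "fragment",
    "probable",
    "by similarity",
)

MIN_ENZYME_LENGTH = 100
MAX_ENZYME_LENGTH = 7000


class Group(Enum):
    ENZYME = "enzyme"
    PUTATIVE = "putative"
    NON_ENZYME = "non_enzyme"


@dataclass(frozen=True)
class RawEntry:
    """One record as parsed from the flat file, before classification."""

    id: str
    description: str
    ec_strings: tuple[str, ...]
    sequence: str


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    sequence: str
    ec_set: frozenset[ECNumber]
    group: Group

    def __post_init__(self) -> None:
        if self.group is Group.ENZYME:
            if not self.ec_set:
                raise ValueError(f"{self.id}: ENZYME record without EC numbers")
            if not MIN_ENZYME_LENGTH <= len(self.sequence) <= MAX_ENZYME_LENGTH:
                raise ValueError(f"{self.id}: ENZYME record outside length bounds")

    @property
    def scoring_ec_set(self) -> frozenset[ECNumber]:
        """EC set as used for scoring: empty unless the record is an enzyme."""
        return self.ec_set if self.group is Group.ENZYME else frozenset()


# ---------------------------------------------------------------------------
# Flat file parsing


def parse_flatfile(stream: TextIO) -> list[RawEntry]:
    """Parse a Swiss-Prot DAT-dialect stream into raw entries.

    Entries are delimited by ``//``; the identifier is the first token on
    the ``ID`` line, descriptions are the concatenated ``DE`` lines (where
    EC numbers appear as ``EC x.x.x.x`` tokens), and the residue lines
    follow ``SQ``.  Malformed entries (missing ID or sequence) are skipped
    with a warning, never a crash.
    """
    entries: list[RawEntry] = []
    entry_id: str | None = None
    de_lines: list[str] = []
    seq_parts: list[str] = []
    in_sq = False

    def flush() -> None:
        nonlocal entry_id, de_lines, seq_parts, in_sq
        if entry_id is not None or de_lines or seq_parts:
            sequence = "".join(seq_parts)
            if entry_id is None or not sequence:
                log.warning(
                    "skipping malformed entry (id=%r, %d residues)",
                    entry_id,
                    len(sequence),
                )
            else:
                description = " ".join(de_lines)
                entries.append(
                    RawEntry(
                        id=entry_id,
                        description=description,
                        ec_strings=tuple(extract_ec_tokens(description)),
                        sequence=sequence,
                    )
                )
        entry_id, de_lines, seq_parts, in_sq = None, [], [], False

    for line in stream:
        line = line.rstrip("\n")
        if line.startswith("//"):
            flush()
        elif line.startswith("ID"):
            tokens = line[2:].split()
            entry_id = tokens[0] if tokens else None
        elif line.startswith("DE"):
            de_lines.append(line[2:].strip())
        elif line.startswith("SQ"):
            in_sq = True
        elif in_sq:
            seq_parts.append(re.sub(r"[\s\d]", "", line).upper())
    flush()
    return entries


def read_fasta_with_annotations(
    fasta: TextIO | str | Path, annotations: TextIO | str | Path
) -> list[RawEntry]:
    """Alternative reader: FASTA plus a TSV table (id, ec_list, description).

    ``ec_list`` is semicolon-separated; unknown ids in the table are
    ignored, sequences without a table row get no ECs and an empty
    description.
    """
    from Bio import SeqIO

    table: dict[str, tuple[str, str]] = {}
    close_ann = False
    if isinstance(annotations, (str, Path)):
        annotations = open(annotations)
        close_ann = True
    try:
        for line in annotations:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rec_id = parts[0]
            ec_list = parts[1] if len(parts) > 1 else ""
            description = parts[2] if len(parts) > 2 else ""
            table[rec_id] = (ec_list, description)
    finally:
        if close_ann:
            annotations.close()

    entries: list[RawEntry] = []
    for rec in SeqIO.parse(fasta, "fasta"):
        ec_list, description = table.get(rec.id, ("", rec.description))
        ecs = tuple(tok for tok in ec_list.split(";") if tok.strip())
        entries.append(
            RawEntry(
                id=rec.id,
                description=description,
                ec_strings=ecs,
                sequence=str(rec.seq).upper(),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Classification


def classify_entry(
    entry: RawEntry,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    min_length: int = MIN_ENZYME_LENGTH,
    max_length: int = MAX_ENZYME_LENGTH,
) -> SequenceRecord:
    """Sort one entry into ENZYME / PUTATIVE / NON_ENZYME.

    Keyword matching is case-insensitive on the description.  EC-bearing
    entries outside the length bounds go to PUTATIVE rather than being
    discarded, so their sequences still contribute neutral (NA) evidence
    during verification.
    """
    description_lc = entry.description.lower()
    ec_set: frozenset[ECNumber] = frozenset()
    for token in entry.ec_strings:
        try:
            ec_set |= {ECNumber.parse(token)}
        except ECParseError:
            log.warning("%s: unparsable EC token %r ignored", entry.id, token)

    if any(kw.lower() in description_lc for kw in keywords):
        group = Group.PUTATIVE
    elif ec_set:
        if min_length <= len(entry.sequence) <= max_length:
            group = Group.ENZYME
        else:
            group = Group.PUTATIVE
    else:
        group = Group.NON_ENZYME
    return SequenceRecord(
        id=entry.id,
        description=entry.description,
        sequence=entry.sequence,
        ec_set=ec_set,
        group=group,
    )


def classify_entries(
    entries: Iterable[RawEntry], **kwargs
) -> list[SequenceRecord]:
    return [classify_entry(e, **kwargs) for e in entries]


# ---------------------------------------------------------------------------
# Redundancy


def is_redundant(q: SequenceRecord, r: SequenceRecord) -> bool:
    """Is ``r`` redundant to ``q``?

    For enzymes: identical sequence and ``ec(r)`` a subset of ``ec(q)``
    (set equality included).  For the other two groups identical sequence
    alone suffices.  Cross-group comparison is a caller bug.
    """
    if q.group is not r.group:
        raise ValueError(
            f"cross-group redundancy comparison: {q.id} ({q.group}) vs "
            f"{r.id} ({r.group})"
        )
    if q.sequence != r.sequence:
        return False
    if q.group is Group.ENZYME:
        return r.ec_set <= q.ec_set
    return True


def deduplicate(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Drop redundant records within each group.

    Candidate retention order is descending EC-set size, then lexicographic
    id, so that when two identical sequences differ in annotation depth the
    EC superset survives.  A record is dropped iff it is redundant to an
    already-retained record.  The original input order of the survivors is
    preserved.
    """
    retained_ids: set[str] = set()
    for group in Group:
        group_records = [r for r in records if r.group is group]
        ordered = sorted(group_records, key=lambda r: (-len(r.ec_set), r.id))
        # bucket by sequence: redundancy requires sequence identity
        kept_by_seq: dict[str, list[SequenceRecord]] = {}
        for rec in ordered:
            kept = kept_by_seq.setdefault(rec.sequence, [])
            if not any(is_redundant(q, rec) for q in kept):
                kept.append(rec)
                retained_ids.add(rec.id)
    return [r for r in records if r.id in retained_ids]


# ---------------------------------------------------------------------------
# EC updates (IUBMB transfers and deletions)


class ECUpdateError(ValueError):
    pass


@dataclass(frozen=True)
class ECUpdateMap:
    """Transferred and deleted EC numbers, as published by the IUBMB."""

    transferred: dict[ECNumber, frozenset[ECNumber]] = field(default_factory=dict)
    deleted: frozenset[ECNumber] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.transferred) & set(self.deleted)
        if overlap:
            raise ECUpdateError(f"ECs both transferred and deleted: {overlap}")


def parse_ec_updates(stream: TextIO) -> ECUpdateMap:
    """Read an update map from TSV: (old_ec, action, new_ecs).

    ``action`` is ``transfer`` or ``delete``; ``new_ecs`` is
    semicolon-separated and only meaningful for transfers.
    """
    transferred: dict[ECNumber, frozenset[ECNumber]] = {}
    deleted: set[ECNumber] = set()
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        old = ECNumber.parse(parts[0])
        action = parts[1].strip().lower()
        if action == "transfer":
            transferred[old] = parse_ec_set(parts[2])
        elif action == "delete":
            deleted.add(old)
        else:
            raise ECUpdateError(f"unknown action {action!r} in update map")
    return ECUpdateMap(transferred=transferred, deleted=frozenset(deleted))


def _dereference(
    ec: ECNumber, updates: ECUpdateMap, max_depth: int
) -> frozenset[ECNumber]:
    current: frozenset[ECNumber] = frozenset({ec})
    for _ in range(max_depth + 1):
        if not any(e in updates.transferred for e in current):
            return current
        nxt: set[ECNumber] = set()
        for e in current:
            nxt |= updates.transferred.get(e, frozenset({e}))
        current = frozenset(nxt)
    raise ECUpdateError(f"transfer chain from {ec} exceeds depth {max_depth} (cycle?)")


def apply_ec_updates(
    records: Sequence[SequenceRecord],
    updates: ECUpdateMap,
    max_depth: int = 5,
) -> list[SequenceRecord]:
    """Apply EC transfers and deletions to the enzyme group.

    Transferred ECs are replaced by their successor set (chains followed up
    to ``max_depth``); deleted ECs are removed from annotations; an enzyme
    whose EC set becomes empty is dropped from the database.
    """
    out: list[SequenceRecord] = []
    for rec in records:
        if rec.group is not Group.ENZYME:
            out.append(rec)
            continue
        new_ecs: set[ECNumber] = set()
        for ec in rec.ec_set:
            new_ecs |= _dereference(ec, updates, max_depth)
        new_ecs -= set(updates.deleted)
        if not new_ecs:
            log.info("%s removed: all EC numbers deleted", rec.id)
            continue
        out.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                sequence=rec.sequence,
                ec_set=frozenset(new_ecs),
                group=rec.group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Persistence: three FASTA files plus a manifest


def write_groups(records: Sequence[SequenceRecord], outdir: str | Path) -> None:
    """Serialize a classified database as one FASTA per group + manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for group in Group:
        with open(outdir / f"{group.value}.fasta", "w") as fh:
            for rec in records:
                if rec.group is group:
                    fh.write(f">{rec.id} {rec.description}\n")
                    for i in range(0, len(rec.sequence), 60):
                        fh.write(rec.sequence[i : i + 60] + "\n")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("id\tgroup\tec_list\tlength\n")
        for rec in records:
            fh.write(
                f"{rec.id}\t{rec.group.value}\t{format_ec_set(rec.ec_set)}\t"
                f"{len(rec.sequence)}\n"
            )


def read_groups(outdir: str | Path) -> list[SequenceRecord]:
    """Inverse of :func:`write_groups`."""
    from Bio import SeqIO

    outdir = Path(outdir)
    meta: dict[str, tuple[Group, frozenset[ECNumber]]] = {}
    with open(outdir / "manifest.tsv") as fh:
        next(fh)  # header
        for line in fh:
            rec_id, group, ec_list, _length = line.rstrip("\n").split("\t")
            meta[rec_id] = (Group(group), parse_ec_set(ec_list))
    records: list[SequenceRecord] = []
    for group in Group:
        path = outdir / f"{group.value}.fasta"
        if not path.exists():
            continue
        for rec in SeqIO.parse(str(path), "fasta"):
            grp, ecs = meta[rec.id]
            description = rec.description.split(" ", 1)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    description=description[1] if len(description) > 1 else "",
                    sequence=str(rec.seq).upper(),
                    ec_set=ecs,
                    group=grp,
                )
            )
    return records


def iter_enzymes(records: Iterable[SequenceRecord]) -> Iterator[SequenceRecord]:
    return (r for r in records if r.group is Group.ENZYME)
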