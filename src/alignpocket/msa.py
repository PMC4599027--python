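"""Multiple sequence alignment containers, I/O, masking and column filtering.

The central object is the immutable :class:`Alignment`; columns removed by
masking or filtering operations are tracked in a :class:`ColumnMask` so the
original column set can always be reconstructed.  Column indices are 0-based
internally; user-facing reports print 1-based positions to match the
residue-numbering convention of the structural-biology literature
(e.g. "Y161").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

from Bio import AlignIO

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("XBZUO")
GAP = "-"
_ALPHABET = STANDARD_AA | AMBIGUOUS_AA | {GAP}

#: default thresholds of the column filter: keep a column iff its gap
#: fraction is strictly below MAX_GAP_FRACTION and its conservation score is
#: strictly above MIN_CONSERVATION.
MAX_GAP_FRACTION = 0.30
MIN_CONSERVATION = 8


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped protein sequences.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, query included.
    seqs:
        Upper-case residue strings over the 20 standard one-letter codes,
        the ambiguity codes X/B/Z/U/O and the gap character ``-``.
    column_annotations:
        Optional per-column annotation strings (e.g. a Stockholm ``#=GC``
        conservation line), each exactly ``length`` characters long.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    column_annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        if not self.seqs:
            raise AlignmentError("empty alignment")
        length = len(self.seqs[0])
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"length mismatch for {sid!r}: {len(seq)} != {length}"
                )
            bad = set(seq) - _ALPHABET
            if bad:
                raise AlignmentError(
                    f"invalid characters {sorted(bad)} in sequence {sid!r}"
                )
        for tag, ann in self.column_annotations.items():
            if len(ann) != length:
                raise AlignmentError(
                    f"column annotation {tag!r} has length {len(ann)} != {length}"
                )

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def column(self, l: int) -> str:
        """Residues of column ``l`` (0-based), in row order."""
        if not 0 <= l < self.length:
            raise IndexError(f"column {l} out of range [0, {self.length})")
        return "".join(seq[l] for seq in self.seqs)

    def take_columns(self, indices: list[int] | tuple[int, ...]) -> "Alignment":
        """New alignment restricted to ``indices`` (original order kept)."""
        idx = list(indices)
        seqs = tuple("".join(seq[i] for i in idx) for seq in self.seqs)
        anns = {
            tag: "".join(ann[i] for i in idx)
            for tag, ann in self.column_annotations.items()
        }
        return Alignment(self.ids, seqs, anns)


@dataclass(frozen=True)
class ColumnMask:
    """Record of which original columns survived a masking/filtering step."""

    kept_indices: tuple[int, ...]
    reason_removed: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.kept_indices) != sorted(set(self.kept_indices)):
            raise ValueError("kept_indices must be strictly increasing")
        overlap = set(self.kept_indices) & set(self.reason_removed)
        if overlap:
            raise ValueError(f"indices both kept and removed: {sorted(overlap)}")

    @property
    def n_removed(self) -> int:
        return len(self.reason_removed)

    def compose(self, inner: "ColumnMask") -> "ColumnMask":
        """Mask equivalent to applying ``self`` first, then ``inner``.

        ``inner`` indexes columns of the alignment *after* ``self`` was
        applied; the composition is expressed in original coordinates.
        """
        kept = tuple(self.kept_indices[i] for i in inner.kept_indices)
        reasons = dict(self.reason_removed)
        for i, why in inner.reason_removed.items():
            reasons[self.kept_indices[i]] = why
        return ColumnMask(kept, reasons)


# ---------------------------------------------------------------------------
# I/O


def _sniff_format(text: str) -> str:
    stripped = text.lstrip()
    if stripped.startswith("# STOCKHOLM"):
        return "stockholm"
    if stripped.startswith(">"):
        return "fasta"
    raise AlignmentError("input is neither FASTA ('>') nor Stockholm ('# STOCKHOLM')")


def read_alignment(text: str) -> Alignment:
    """Parse FASTA or Stockholm alignment text (dialect auto-detected).

    Stockholm per-column ``#=GC`` annotation lines are retained in
    ``column_annotations`` under their tag names.  Lower-case residues are
    upper-cased and the Stockholm insert gap ``.`` is normalised to ``-``.

    Raises
    ------
    AlignmentError
        On empty input, unknown dialect, ragged rows (the error names the
        offending id) or invalid residue characters.
    """
    if not text.strip():
        raise AlignmentError("empty alignment input")
    fmt = _sniff_format(text)
    try:
        bio = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        # Biopython reports ragged FASTA rows with a generic message; re-scan
        # to name the offending record.
        if fmt == "fasta":
            _raise_ragged_fasta(text)
        raise AlignmentError(str(exc)) from exc
    ids = tuple(rec.id for rec in bio)
    seqs = tuple(str(rec.seq).upper().replace(".", GAP) for rec in bio)
    anns: dict[str, str] = {}
    for tag, ann in getattr(bio, "column_annotations", {}).items():
        anns[tag.removeprefix("GC:")] = ann
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        longest = max(lengths)
        for sid, seq in zip(ids, seqs):
            if len(seq) != longest:
                raise AlignmentError(
                    f"length mismatch for {sid!r}: {len(seq)} != {longest}"
                )
    return Alignment(ids, seqs, anns)


def _raise_ragged_fasta(text: str) -> None:
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    ref = len(records[0].seq)
    for rec in records[1:]:
        if len(rec.seq) != ref:
            raise AlignmentError(
                f"length mismatch for {rec.id!r}: {len(rec.seq)} != {ref}"
            )
    raise AlignmentError("alignment could not be parsed")


def write_alignment(aln: Alignment, fmt: str = "fasta") -> str:
    """Serialise to FASTA or Stockholm text.

    The Stockholm writer emits every entry of ``column_annotations`` as a
    ``#=GC`` line so that read -> write -> read is lossless for both
    sequences and annotations.
    """
    if fmt == "fasta":
        out = []
        for sid, seq in zip(aln.ids, aln.seqs):
            out.append(f">{sid}")
            for i in range(0, len(seq), 60):
                out.append(seq[i : i + 60])
        return "\n".join(out) + "\n"
    if fmt == "stockholm":
        width = max(
            [len(i) for i in aln.ids]
            + [len(f"#=GC {t}") for t in aln.column_annotations]
            or [0]
        )
        lines = ["# STOCKHOLM 1.0"]
        for sid, seq in zip(aln.ids, aln.seqs):
            lines.append(f"{sid:<{width}} {seq}")
        for tag, ann in aln.column_annotations.items():
            lines.append(f"{f'#=GC {tag}':<{width}} {ann}")
        lines.append("//")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Masking and filtering


def mask_query_insertions(aln: Alignment, query_id: str) -> tuple[Alignment, ColumnMask]:
    """Hide columns where the query has a gap (insertions relative to it).

    Downstream per-residue scores are indexed along the ungapped query, so
    every column in which the query is ``-`` is removed and recorded in the
    mask with reason ``query_gap``.
    """
    query = aln.row(query_id)
    kept = tuple(i for i, aa in enumerate(query) if aa != GAP)
    removed = {i: "query_gap" for i, aa in enumerate(query) if aa == GAP}
    return aln.take_columns(kept), ColumnMask(kept, removed)


def column_gap_fraction(aln: Alignment, l: int) -> float:
    """Fraction of rows with ``-`` in column ``l``; ambiguity codes count
    as residues, not gaps."""
    col = aln.column(l)
    return col.count(GAP) / len(col)


def conservation_score(
    aln: Alignment, l: int, annotation_tag: str | None = None
) -> int:
    """Integer conservation score 0..10 for column ``l``.

    If the alignment carries an explicit per-column conservation annotation
    (a Stockholm ``#=GC`` line whose tag contains ``cons``, or the tag named
    via ``annotation_tag``) with a digit at ``l``, that digit wins.
    Otherwise the score falls back to ``floor(10 * p_modal)`` where
    ``p_modal`` is the proportion of the single most frequent standard
    residue among the non-gap entries of the column.  An all-gap column
    scores 0.
    """
    ann = _conservation_annotation(aln, annotation_tag)
    if ann is not None:
        ch = ann[l] if l < len(ann) else ""
        if ch.isdigit():
            return int(ch)
        if ch == "*":  # some tools print '*' for a fully conserved column
            return 10
    col = aln.column(l)
    residues = [aa for aa in col if aa != GAP]
    if not residues:
        return 0
    counts: dict[str, int] = {}
    for aa in residues:
        if aa in STANDARD_AA:  # ambiguity codes never count as the mode
            counts[aa] = counts.get(aa, 0) + 1
    if not counts:
        return 0
    return int(10 * max(counts.values()) / len(residues))


def _conservation_annotation(aln: Alignment, tag: str | None) -> str | None:
    if tag is not None:
        return aln.column_annotations.get(tag)
    for name, ann in aln.column_annotations.items():
        low = name.lower()
        if "cons" in low and "ss" not in low:  # skip SS_cons secondary structure
            return ann
    return None


def filter_columns(
    aln: Alignment,
    max_gap: float = MAX_GAP_FRACTION,
    min_cons: int = MIN_CONSERVATION,
    annotation_tag: str | None = None,
) -> tuple[Alignment, ColumnMask]:
    """Keep columns with gap fraction strictly below ``max_gap`` AND
    conservation score strictly above ``min_cons``.

    Both inequalities are strict: a column at exactly 30% gaps or with a
    score of exactly 8 is removed.  Removal reasons are recorded as
    ``gap_fraction`` or ``low_conservation`` (gap test applied first).
    """
    if not 0.0 <= max_gap <= 1.0:
        raise ValueError("max_gap must lie in [0, 1]")
    kept: list[int] = []
    removed: dict[int, str] = {}
    for l in range(aln.length):
        if not column_gap_fraction(aln, l) < max_gap:
            removed[l] = "gap_fraction"
        elif not conservation_score(aln, l, annotation_tag) > min_cons:
            removed[l] = "low_conservation"
        else:
            kept.append(l)
    return aln.take_columns(kept), ColumnMask(tuple(kept), removed)
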