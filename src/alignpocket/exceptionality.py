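"""Per-residue exceptionality scoring on a multiple alignment.

The score asks, for each residue of a query protein: how unexpected is the
physicochemical category of this residue, given what its homologs carry in
the same alignment column?  The twenty standard amino acids are partitioned
into six categories (aliphatic, aromatic, polar, positive, negative,
special).  For column ``l`` with category proportions ``P_i(l)`` over the
homologs, the category entropy is

    s(l) = - sum_i P_i(l) * log(P_i(l)),        (natural log, empty
                                                 categories ignored)

and the exceptionality of the query residue whose category has proportion
``P_q(l)`` is

    S(l) = (P_max(l) - P_q(l)) / s(l),

where ``P_max(l)`` is the proportion of the most abundant category — the
category one *expects* at that position.  S is zero when the query sits in
the modal category, grows as the query strays from a well-conserved
consensus, and is flagged infinite when a perfectly conserved column
(s = 0) carries a deviant query residue.  Columns with more than 50% gaps
among the homologs are masked: their entropy is pinned to 0 and no score is
reported.

The log base is a global scale factor on every finite score, so rankings do
not depend on it; natural log is used throughout.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .msa import GAP, Alignment, mask_query_insertions

#: The six physicochemical categories.  Disjoint, and together they cover
#: the 20 standard residues exactly.
CATEGORIES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AVLIMC"),
    "aromatic": frozenset("FWYH"),
    "polar": frozenset("STNQ"),
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
    "special": frozenset("GP"),
}

CATEGORY_NAMES = tuple(CATEGORIES)

_RESIDUE_TO_CATEGORY = {
    aa: name for name, members in CATEGORIES.items() for aa in members
}

#: Columns whose homolog gap fraction exceeds this are masked.
GAP_MASK_THRESHOLD = 0.50

MAX_ENTROPY = math.log(len(CATEGORIES))


class Status(str, enum.Enum):
    """Classification of a per-position score."""

    FINITE = "finite"
    ZERO = "zero"
    INFINITE = "infinite"
    MASKED = "masked"


def residue_category(aa: str) -> str | None:
    """Category name for a one-letter residue code.

    Ambiguity codes (X, B, Z, U, O) and the gap character map to ``None``.
    """
    if len(aa) != 1:
        raise ValueError(f"expected a single character, got {aa!r}")
    return _RESIDUE_TO_CATEGORY.get(aa.upper())


@dataclass(frozen=True)
class ColumnProfile:
    """Category composition of one alignment column (query excluded).

    ``proportions`` are computed over the non-query rows, with gaps and
    ambiguity codes excluded from both numerator and denominator.
    ``masked`` is true when the gap fraction among non-query rows exceeds
    50%, in which case the entropy is pinned to 0.
    """

    proportions: Mapping[str, float]
    gap_fraction: float
    n_effective: int
    entropy: float
    p_max: float
    masked: bool


@dataclass(frozen=True)
class ExceptionalityProfile:
    """Scores along the ungapped query, 1-based residue numbering."""

    query_id: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    scores: tuple[float, ...]  # inf for INFINITE, nan for MASKED
    statuses: tuple[Status, ...]
    profiles: tuple[ColumnProfile, ...] = field(repr=False, default=())

    def __len__(self) -> int:
        return len(self.positions)


def _category_entropy(proportions: Mapping[str, float]) -> float:
    return -sum(p * math.log(p) for p in proportions.values() if p > 0.0)


def column_profile(
    aln: Alignment,
    query_id: str,
    l: int,
    include_query: bool = False,
    gap_mask_threshold: float = GAP_MASK_THRESHOLD,
) -> ColumnProfile:
    """Category proportions, gap fraction and entropy for column ``l``.

    ``include_query=True`` counts the query row too (sensitivity checks);
    the default follows the convention that the column distribution is the
    homologs' and the query is evaluated against it.
    """
    qidx = aln.ids.index(query_id) if query_id in aln.ids else None
    if qidx is None:
        raise KeyError(f"unknown query id {query_id!r}")
    col = aln.column(l)
    rows = [
        aa for i, aa in enumerate(col) if include_query or i != qidx
    ]
    n_rows = len(rows)
    n_gaps = sum(1 for aa in rows if aa == GAP)
    gap_fraction = n_gaps / n_rows if n_rows else 1.0
    counts = dict.fromkeys(CATEGORY_NAMES, 0)
    for aa in rows:
        cat = _RESIDUE_TO_CATEGORY.get(aa)
        if cat is not None:
            counts[cat] += 1
    n_eff = sum(counts.values())
    masked = gap_fraction > gap_mask_threshold
    if n_eff == 0 and not masked:
        warnings.warn(
            f"column {l}: no scoreable residues among homologs; masking",
            stacklevel=2,
        )
        masked = True
    if masked or n_eff == 0:
        props: dict[str, float] = dict.fromkeys(CATEGORY_NAMES, 0.0)
        return ColumnProfile(props, gap_fraction, n_eff, 0.0, 0.0, True)
    props = {name: counts[name] / n_eff for name in CATEGORY_NAMES}
    return ColumnProfile(
        props,
        gap_fraction,
        n_eff,
        _category_entropy(props),
        max(props.values()),
        False,
    )


def column_entropy(profile: ColumnProfile) -> float:
    """Category entropy in nats; 0 for masked columns by the gap rule."""
    return 0.0 if profile.masked else _category_entropy(profile.proportions)


def exceptionality_score(
    aln: Alignment,
    query_id: str,
    l: int,
    include_query: bool = False,
) -> tuple[float, Status]:
    """Score ``(P_max - P_query_category) / s`` for one kept column.

    Returns ``(0.0, Status.ZERO)`` when the query's category attains the
    modal proportion, ``(inf, Status.INFINITE)`` when a zero-entropy column
    carries a deviant query, and ``(nan, Status.MASKED)`` when the >50%-gap
    rule fired.
    """
    q_aa = aln.row(query_id)[l]
    if q_aa == GAP:
        raise ValueError(
            f"query has a gap at column {l}; apply mask_query_insertions first"
        )
    profile = column_profile(aln, query_id, l, include_query=include_query)
    return _score_from_profile(profile, q_aa)


def _score_from_profile(profile: ColumnProfile, q_aa: str) -> tuple[float, Status]:
    if profile.masked:
        return math.nan, Status.MASKED
    q_cat = _RESIDUE_TO_CATEGORY.get(q_aa)
    p_query = profile.proportions[q_cat] if q_cat is not None else 0.0
    numerator = profile.p_max - p_query
    if numerator == 0.0:
        return 0.0, Status.ZERO
    if profile.entropy == 0.0:
        return math.inf, Status.INFINITE
    return numerator / profile.entropy, Status.FINITE


def exceptionality_profile(
    aln: Alignment,
    query_id: str,
    include_query: bool = False,
) -> ExceptionalityProfile:
    """Score every residue of the query along the ungapped query sequence.

    Columns where the query has a gap are first hidden
    (:func:`alignpocket.msa.mask_query_insertions`); the remaining columns
    map 1:1 onto query residues, numbered from 1.
    """
    masked_aln, _ = mask_query_insertions(aln, query_id)
    query = masked_aln.row(query_id)
    positions, residues, scores, statuses, profiles = [], [], [], [], []
    for l, aa in enumerate(query):
        profile = column_profile(masked_aln, query_id, l, include_query=include_query)
        value, status = _score_from_profile(profile, aa)
        positions.append(l + 1)
        residues.append(aa)
        scores.append(value)
        statuses.append(status)
        profiles.append(profile)
    return ExceptionalityProfile(
        query_id,
        tuple(positions),
        tuple(residues),
        tuple(scores),
        tuple(statuses),
        tuple(profiles),
    )


def rank_exceptional(profile: ExceptionalityProfile, k: int) -> pd.DataFrame:
    """Top-``k`` most exceptional positions as a report table.

    Ordering: infinite scores first, then finite scores descending, ties
    broken by ascending position.  Masked positions carry no score and are
    excluded.  If fewer than ``k`` scoreable positions exist, all are
    returned (the report's ``truncated`` attribute notes this).

    Columns: position (1-based), residue, category, P_i, P_max, entropy,
    score, status.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for pos, aa, score, status, colp in zip(
        profile.positions,
        profile.residues,
        profile.scores,
        profile.statuses,
        profile.profiles,
    ):
        if status is Status.MASKED:
            continue
        cat = _RESIDUE_TO_CATEGORY.get(aa)
        p_i = colp.proportions[cat] if cat is not None else 0.0
        modal = max(colp.proportions, key=colp.proportions.__getitem__)
        rows.append(
            {
                "position": pos,
                "residue": aa,
                "category": cat,
                "modal_category": modal,
                "P_i": p_i,
                "P_max": colp.p_max,
                "entropy": colp.entropy,
                "score": score,
                "status": status.value,
            }
        )
    rows.sort(
        key=lambda r: (
            0 if r["status"] == Status.INFINITE.value else 1,
            -r["score"] if math.isfinite(r["score"]) else 0.0,
            r["position"],
        )
    )
    report = pd.DataFrame(rows[:k], columns=[
        "position", "residue", "category", "modal_category",
        "P_i", "P_max", "entropy", "score", "status",
    ])
    report.attrs["truncated"] = len(rows) < k
    return report
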