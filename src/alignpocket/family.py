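"""Profile-HMM E-value panel screening and family assignment.

A screen runs several family profile HMMs against a set of candidate
proteins and records the E-value of each (family, protein) pair; absent
entries mean the search returned no hit worth reporting.  This module turns
such a panel into per-protein family calls: the best (smallest-E) family,
whether the call clears the significance threshold (E <= 0.05 by default),
and how many orders of magnitude separate the best from the second-best
family — the quantity that makes a call convincing for highly divergent
proteins where absolute E-values are modest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: E-values above this are not significant (strictly greater than → not
#: significant, hence the boundary itself is significant).
DEFAULT_ALPHA = 0.05

_MISSING_TOKENS = {"", "-", "–", "—", "na", "NA", "NaN", "nan", "."}


class EvalueTableError(ValueError):
    """Raised for malformed E-value table input."""


@dataclass(frozen=True)
class EvalueTable:
    """Families x proteins matrix of E-values with missing entries.

    ``values`` is indexed by family name (rows) and protein id (columns);
    missing entries are NaN.  ``models`` maps each family name to its
    profile-HMM model identifier (may be empty strings).
    """

    values: pd.DataFrame
    models: dict[str, str]

    def __post_init__(self) -> None:
        present = self.values.to_numpy(dtype=float)
        if np.any(present[~np.isnan(present)] <= 0):
            raise EvalueTableError("E-values must be positive")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass(frozen=True)
class FamilyCall:
    """Assignment of one protein to its best-matching family."""

    protein: str
    best_family: str | None
    best_model: str | None
    best_evalue: float | None
    second_family: str | None
    second_evalue: float | None
    separation_magnitude: int | None
    significant: bool
    tied_families: tuple[str, ...] = ()

    @property
    def assigned(self) -> bool:
        """True when a significant best family exists."""
        return self.best_family is not None and self.significant


def read_evalue_table(text: str) -> EvalueTable:
    """Parse a TSV E-value panel.

    Layout: a header line ``family<TAB>model<TAB><protein ids...>`` (the
    ``model`` column is optional) followed by one line per family.  The
    tokens ``-``, ``–`` and empty cells denote missing entries.  Scientific
    notation such as ``4.90e-12`` is accepted.

    Raises
    ------
    EvalueTableError
        On an empty table or a non-numeric non-missing cell (the error
        names the family row and protein column).
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise EvalueTableError("empty E-value table")
    header = lines[0].split("\t")
    has_model = len(header) > 1 and header[1].strip().lower() in {"model", "pfam", "hmm"}
    proteins = [h.strip() for h in header[(2 if has_model else 1):]]
    if not proteins:
        raise EvalueTableError("no protein columns in header")
    families: list[str] = []
    models: dict[str, str] = {}
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        fam = cells[0].strip()
        model = cells[1].strip() if has_model and len(cells) > 1 else ""
        data = cells[(2 if has_model else 1):]
        data += [""] * (len(proteins) - len(data))
        parsed: list[float] = []
        for prot, cell in zip(proteins, data):
            tok = cell.strip()
            if tok in _MISSING_TOKENS:
                parsed.append(math.nan)
                continue
            try:
                value = float(tok)
            except ValueError:
                raise EvalueTableError(
                    f"non-numeric E-value {tok!r} at family {fam!r}, protein {prot!r}"
                ) from None
            parsed.append(value)
        families.append(fam)
        models[fam] = model
        rows.append(parsed)
    frame = pd.DataFrame(rows, index=families, columns=proteins, dtype=float)
    return EvalueTable(frame, models)


def significant_hits(table: EvalueTable, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Boolean mask of entries that are present and have E <= alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return table.values.le(alpha) & table.values.notna()


def separation_magnitude(best_e: float, second_e: float) -> int:
    """Order-of-magnitude gap between best and second-best E-values.

    ``round(log10(second / best))``: the integer k such that the best hit is
    about 10^k times smaller than the runner-up.
    """
    if best_e <= 0 or second_e <= 0:
        raise ValueError("E-values must be positive")
    if best_e > second_e:
        raise ValueError("best E-value must not exceed the second-best")
    return round(math.log10(second_e / best_e))


def assign_family(
    table: EvalueTable, protein: str, alpha: float = DEFAULT_ALPHA
) -> FamilyCall:
    """Call the family of ``protein`` from its E-value column.

    The best family minimises E over present entries; the call is
    significant iff that E is <= ``alpha``.  Ties for best are broken by
    family order in the table and reported in ``tied_families``.  With no
    present entry, or none significant, the protein is unassigned
    (``assigned`` is False).
    """
    if protein not in table.values.columns:
        raise KeyError(f"unknown protein {protein!r}")
    col = table.values[protein]
    present = col.dropna()
    if present.empty:
        return FamilyCall(protein, None, None, None, None, None, None, False)
    order = present.sort_values(kind="stable")  # stable: table order breaks ties
    best_family = str(order.index[0])
    best_e = float(order.iloc[0])
    ties = tuple(str(f) for f in order.index[order.values == best_e])
    second_family: str | None = None
    second_e: float | None = None
    sep: int | None = None
    if len(order) > 1:
        second_family = str(order.index[1])
        second_e = float(order.iloc[1])
        sep = separation_magnitude(best_e, second_e)
    return FamilyCall(
        protein,
        best_family,
        table.models.get(best_family),
        best_e,
        second_family,
        second_e,
        sep,
        best_e <= alpha,
        ties if len(ties) > 1 else (),
    )


def screen(table: EvalueTable, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Family calls for every protein in the panel, as a report table."""
    rows = []
    for protein in table.proteins:
        call = assign_family(table, protein, alpha)
        rows.append(
            {
                "protein": call.protein,
                "best_family": call.best_family,
                "best_model": call.best_model,
                "best_evalue": call.best_evalue,
                "second_family": call.second_family,
                "second_evalue": call.second_evalue,
                "separation_magnitude": call.separation_magnitude,
                "significant": call.significant,
                "assigned": call.assigned,
            }
        )
    return pd.DataFrame(rows)
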