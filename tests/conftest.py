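"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from alignpocket.msa import Alignment

CATEGORY_OF = {}
for _name, _members in {
    "aliphatic": "AVLIMC",
    "aromatic": "FWYH",
    "polar": "STNQ",
    "positive": "KR",
    "negative": "DE",
    "special": "GP",
}.items():
    for _aa in _members:
        CATEGORY_OF[_aa] = _name

ALL_RESIDUES = "".join(sorted(CATEGORY_OF))


def oracle_column_stats(homolog_residues: str, query_aa: str):
    """Exhaustive-counting oracle for one column (independent of the package).

    Counts categories one residue at a time, computes proportions, gap
    fraction, natural-log entropy over non-empty categories, and the score
    (p_max - p_query) / entropy with its status.  Mirrors the statistic's
    definition directly; shares no code with alignpocket.
    """
    n_rows = len(homolog_residues)
    gaps = sum(1 for aa in homolog_residues if aa == "-")
    counts: dict[str, int] = {}
    for aa in homolog_residues:
        cat = CATEGORY_OF.get(aa)
        if cat is not None:
            counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    gap_fraction = gaps / n_rows if n_rows else 1.0
    if gap_fraction > 0.5 or total == 0:
        return {"masked": True, "gap_fraction": gap_fraction, "entropy": 0.0}
    props = {cat: cnt / total for cat, cnt in counts.items()}
    entropy = 0.0
    for p in props.values():
        entropy -= p * math.log(p)
    p_max = max(props.values())
    p_query = props.get(CATEGORY_OF.get(query_aa), 0.0)
    if p_max - p_query == 0.0:
        score, status = 0.0, "zero"
    elif entropy == 0.0:
        score, status = math.inf, "infinite"
    else:
        score, status = (p_max - p_query) / entropy, "finite"
    return {
        "masked": False,
        "gap_fraction": gap_fraction,
        "proportions": props,
        "entropy": entropy,
        "p_max": p_max,
        "score": score,
        "status": status,
    }


def random_column(rng: np.random.Generator, n_rows: int) -> tuple[str, str]:
    """A random homolog column (may contain gaps) plus a random non-gap query."""
    pool = ALL_RESIDUES + "-" * 4 + "X"
    col = "".join(pool[rng.integers(len(pool))] for _ in range(n_rows))
    query = ALL_RESIDUES[rng.integers(len(ALL_RESIDUES))]
    return col, query


def column_alignment(homolog_residues: str, query_aa: str) -> Alignment:
    """Single-column alignment with the query as the first row."""
    ids = ("query",) + tuple(f"h{i}" for i in range(len(homolog_residues)))
    return Alignment(ids, (query_aa,) + tuple(homolog_residues))


@pytest.fixture
def rng():
    return np.random.default_rng(20151009)
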