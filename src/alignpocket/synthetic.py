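"""Seeded generators producing inputs with known ground truth.

Every analysis stage in this package has a matching generator here:

* :func:`gen_alignment` — alignment columns with prescribed category
  compositions, gap noise, and planted deviant query residues whose
  expected exceptionality score is computed independently of the
  :mod:`alignpocket.exceptionality` module (closed-form arithmetic kept
  textually separate, so generator and analyser can check each other);
* :func:`gen_evalue_table` — E-value panels with a planted winning family
  and a prescribed order-of-magnitude separation;
* :func:`gen_trajectory` — toy multi-model PDB trajectories with planted
  hydrogen-bond on/off schedules, scheduled ring stacking geometry,
  restraint-violating frames and a Gaussian probe-pair distance process.

Defaults emulate the study conditions this toolkit was built around:
23 homologs in the alignment (the size of a curated ligase structure
panel), 50-frame trajectories with an 86% hydrogen-bond occupancy schedule
and an 18% restraint-violation schedule.  The same seed always yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .family import EvalueTable
from .msa import Alignment

# The category partition, restated locally: ground truths below must not
# depend on the analysis modules they are used to verify.
_CATEGORIES: dict[str, str] = {
    "aliphatic": "AVLIMC",
    "aromatic": "FWYH",
    "polar": "STNQ",
    "positive": "KR",
    "negative": "DE",
    "special": "GP",
}
_CATEGORY_NAMES = tuple(_CATEGORIES)


class RecipeError(ValueError):
    """Raised when a recipe is internally inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Alignments with planted deviant residues


@dataclass(frozen=True)
class PlantedDeviant:
    """A query position made deliberately exceptional.

    The column receives ``n_homologs - n_minority`` residues of
    ``majority_category`` and ``n_minority`` of ``query_category``; the
    query residue is drawn from ``query_category``.  With ``n_minority=0``
    the column is perfectly conserved and the planted score is infinite.
    """

    position: int  # 1-based along the (ungapped) query
    query_category: str = "aromatic"
    majority_category: str = "aliphatic"
    n_minority: int = 3

    def __post_init__(self) -> None:
        for cat in (self.query_category, self.majority_category):
            if cat not in _CATEGORIES:
                raise RecipeError(f"unknown category {cat!r}")
        if self.query_category == self.majority_category:
            raise RecipeError("deviant query category must differ from the majority")
        if self.n_minority < 0:
            raise RecipeError("n_minority must be >= 0")


@dataclass(frozen=True)
class AlignmentRecipe:
    """Recipe for a synthetic alignment with known per-position truth.

    Background columns pick one category for the column; each homolog
    deviates from it with probability ``noise`` (capped at a quarter of the
    rows so the background category always stays modal), and the query
    matches the background category, making the true score exactly 0.
    ``gap_prob`` introduces homolog gaps; ``query_gap_prob`` introduces
    query gaps (columns later hidden as insertions relative to the query).
    """

    n_homologs: int = 23
    length: int = 60
    planted: tuple[PlantedDeviant, ...] = ()
    noise: float = 0.10
    gap_prob: float = 0.05
    query_gap_prob: float = 0.0
    query_id: str = "query"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_homologs < 2:
            raise RecipeError("need at least 2 homologs")
        if not 0 <= self.noise < 0.5:
            raise RecipeError("noise must lie in [0, 0.5)")
        positions = [p.position for p in self.planted]
        if len(set(positions)) != len(positions):
            raise RecipeError("planted positions must be distinct")
        for p in self.planted:
            if not 1 <= p.position <= self.length:
                raise RecipeError(f"planted position {p.position} outside 1..{self.length}")
            if p.n_minority > self.n_homologs // 2:
                raise RecipeError("minority count must stay below half the homologs")
            if p.n_minority == 0 and p.query_category == p.majority_category:
                raise RecipeError("zero-entropy column cannot carry a same-category deviant")


def _truth_score(counts: dict[str, int], query_category: str) -> tuple[float, str]:
    """Closed-form expected score from a realized column composition.

    Independent restatement of the statistic: proportions over the homolog
    counts, natural-log category entropy ignoring empty categories, score
    (p_max - p_query) / entropy.  Returns (value, status).
    """
    total = sum(counts.values())
    if total == 0:
        return math.nan, "masked"
    props = {c: n / total for c, n in counts.items() if n > 0}
    p_max = max(props.values())
    p_query = props.get(query_category, 0.0)
    if p_max == p_query:
        return 0.0, "zero"
    entropy = -sum(p * math.log(p) for p in props.values())
    if entropy == 0.0:
        return math.inf, "infinite"
    return (p_max - p_query) / entropy, "finite"


def gen_alignment(
    recipe: AlignmentRecipe, rng: np.random.Generator | None = None
) -> tuple[Alignment, pd.DataFrame]:
    """Generate an alignment and its per-position ground-truth table.

    The truth table has one row per query position (1-based), with the
    realized column composition's expected score and status, and a
    ``planted`` flag.  Gap noise never applies to planted columns, and a
    homolog row never exceeds the 50% gap-masking threshold by
    construction (gap draws are capped per column).
    """
    rng = np.random.default_rng(recipe.seed) if rng is None else rng
    n, length = recipe.n_homologs, recipe.length
    planted_by_pos = {p.position: p for p in recipe.planted}

    homologs = [[None] * length for _ in range(n)]
    query: list[str] = []
    truth_rows = []

    def _draw(cat: str) -> str:
        members = _CATEGORIES[cat]
        return members[rng.integers(len(members))]

    max_noise = n // 4
    max_gaps = (n - 1) // 2  # keep gap fraction at or below 50%

    for pos in range(1, length + 1):
        col = pos - 1
        plant = planted_by_pos.get(pos)
        if plant is not None:
            counts = {
                plant.majority_category: n - plant.n_minority,
                plant.query_category: plant.n_minority,
            }
            residues = [_draw(plant.majority_category) for _ in range(n - plant.n_minority)]
            residues += [_draw(plant.query_category) for _ in range(plant.n_minority)]
            order = rng.permutation(n)
            for row, res in zip(order, residues):
                homologs[row][col] = res
            query.append(_draw(plant.query_category))
            value, status = _truth_score(counts, plant.query_category)
            if status == "zero":
                raise RecipeError(
                    f"planted deviant at {pos} is not deviant for this composition"
                )
            truth_rows.append((pos, value, status, True))
            continue

        background = _CATEGORY_NAMES[rng.integers(len(_CATEGORY_NAMES))]
        n_noise = min(int(rng.binomial(n, recipe.noise)), max_noise)
        n_gaps = min(int(rng.binomial(n, recipe.gap_prob)), max_gaps)
        n_gaps = min(n_gaps, n - n_noise)
        n_background = n - n_noise - n_gaps
        counts = {background: n_background}
        residues = [_draw(background) for _ in range(n_background)]
        others = [c for c in _CATEGORY_NAMES if c != background]
        for _ in range(n_noise):
            cat = others[rng.integers(len(others))]
            counts[cat] = counts.get(cat, 0) + 1
            residues.append(_draw(cat))
        residues += ["-"] * n_gaps
        order = rng.permutation(n)
        for row, res in zip(order, residues):
            homologs[row][col] = res
        query.append(_draw(background))
        value, status = _truth_score(counts, background)
        truth_rows.append((pos, value, status, False))

    query_seq = "".join(query)
    if recipe.query_gap_prob > 0:
        gaps = rng.random(length) < recipe.query_gap_prob
        for p in planted_by_pos:  # planted positions always survive masking
            gaps[p - 1] = False
        query_seq = "".join(
            "-" if g else aa for aa, g in zip(query_seq, gaps)
        )
        kept = [i for i, g in enumerate(gaps) if not g]
        truth_rows = [
            (rank + 1, truth_rows[i][1], truth_rows[i][2], truth_rows[i][3])
            for rank, i in enumerate(kept)
        ]

    ids = (recipe.query_id,) + tuple(f"homolog{i + 1:03d}" for i in range(n))
    seqs = (query_seq,) + tuple("".join(row) for row in homologs)
    truth = pd.DataFrame(
        truth_rows, columns=["position", "expected_score", "status", "planted"]
    )
    return Alignment(ids, seqs), truth


# ---------------------------------------------------------------------------
# E-value panels with a planted winner


def gen_evalue_table(
    n_families: int,
    n_proteins: int,
    winner_family: int = 0,
    separation_magnitude: int = 7,
    seed: int = 0,
    alpha: float = 0.05,
    missing_prob: float = 0.25,
) -> tuple[EvalueTable, pd.DataFrame]:
    """Panel with one planted winning family per protein column.

    For every protein, the winner's E-value is log-uniform below
    ``alpha / 10^m`` (m = ``separation_magnitude``), the runner-up sits a
    factor ``10^m * u`` above it with jitter ``u ~ U[0.8, 1.2]`` (so the
    rounded log10 separation recovers m exactly), and the remaining
    families are either missing or drawn above ``alpha``.

    Returns the table and a truth frame with columns protein,
    winner_family, separation.
    """
    if separation_magnitude < 1:
        raise RecipeError("separation magnitude must be >= 1")
    if not 0 <= winner_family < n_families:
        raise RecipeError("winner_family index out of range")
    if n_families < 2:
        raise RecipeError("need at least 2 families for a runner-up")
    rng = np.random.default_rng(seed)
    families = [f"FAM{i + 1:02d}" for i in range(n_families)]
    models = {fam: f"MODEL{i + 1:04d}" for i, fam in enumerate(families)}
    proteins = [f"protein{j + 1:02d}" for j in range(n_proteins)]
    values = np.full((n_families, n_proteins), np.nan)
    truth_rows = []
    for j in range(n_proteins):
        ceiling = alpha / 10.0**separation_magnitude
        winner_e = 10.0 ** rng.uniform(math.log10(ceiling) - 2.0, math.log10(ceiling))
        runner_e = winner_e * 10.0**separation_magnitude * rng.uniform(0.8, 1.2)
        other_rows = [i for i in range(n_families) if i != winner_family]
        runner_row = other_rows[rng.integers(len(other_rows))]
        values[winner_family, j] = winner_e
        values[runner_row, j] = runner_e
        for i in other_rows:
            if i == runner_row:
                continue
            if rng.random() < missing_prob:
                continue  # stays missing
            values[i, j] = rng.uniform(max(alpha * 1.2, runner_e), 1.0)
        truth_rows.append((proteins[j], families[winner_family], separation_magnitude))
    frame = pd.DataFrame(values, index=families, columns=proteins)
    truth = pd.DataFrame(truth_rows, columns=["protein", "winner_family", "separation"])
    return EvalueTable(frame, models), truth


# ---------------------------------------------------------------------------
# Toy trajectories


@dataclass(frozen=True)
class TrajectoryRecipe:
    """Schedules for a toy multi-model PDB trajectory.

    Four independent atom groups, placed far apart so they cannot
    interfere:

    * an N-H donor (resid 1) and an O acceptor (resid 2) realizing the
      hydrogen-bond on/off schedule — "on" frames are placed well inside
      the 3.0 A / 30 deg criteria, "off" frames outside (by distance or by
      angle, per ``hbond_off_mode``);
    * two benzene-like rings (resids 3 and 4) at scheduled centroid
      distance and inter-plane angle;
    * a restraint atom pair (resids 5 and 6) whose distance sits at the
      restraint centre r_i on quiet frames and outside [r0, r1] on
      violating frames;
    * a probe pair (resids 7 and 8) with Gaussian distances for
      distance-statistics checks.

    Schedule arrays must have ``n_frames`` entries.  Defaults reproduce the
    bench-mark occupancy (43/50 frames = 86%) and restraint-violation
    (9/50 = 18%) fractions.
    """

    n_frames: int = 50
    hbond_on: tuple[bool, ...] = ()
    hbond_off_mode: str = "distance"  # or "angle"
    stack_distance_A: tuple[float, ...] = ()
    stack_angle_deg: tuple[float, ...] = ()
    restraint_r_i_nm: float = 0.45
    violating: tuple[bool, ...] = ()
    pair_mean_A: float = 7.7
    pair_sd_A: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "hbond_on", _default_schedule(self.hbond_on, self.n_frames, 43, 50)
        )
        object.__setattr__(
            self, "violating", _default_schedule(self.violating, self.n_frames, 9, 50)
        )
        if not self.stack_distance_A:
            object.__setattr__(self, "stack_distance_A", (3.5,) * self.n_frames)
        if not self.stack_angle_deg:
            object.__setattr__(self, "stack_angle_deg", (5.0,) * self.n_frames)
        for name in ("hbond_on", "violating", "stack_distance_A", "stack_angle_deg"):
            if len(getattr(self, name)) != self.n_frames:
                raise RecipeError(f"{name} must have {self.n_frames} entries")
        if self.hbond_off_mode not in {"distance", "angle"}:
            raise RecipeError("hbond_off_mode must be 'distance' or 'angle'")
        if self.pair_mean_A <= 1.0:
            raise RecipeError("probe pair mean distance must exceed 1 A")


def _default_schedule(given, n_frames: int, on_num: int, on_den: int) -> tuple[bool, ...]:
    if given:
        return tuple(bool(v) for v in given)
    n_on = round(n_frames * on_num / on_den)
    return tuple(i < n_on for i in range(n_frames))


def deviant_trajectory_recipe(n_frames: int = 50, seed: int = 0) -> TrajectoryRecipe:
    """Recipe emulating a non-stacked, restraint-straining conformation:
    rings at 5.79 A / 52 deg every frame, 18% violating frames."""
    return TrajectoryRecipe(
        n_frames=n_frames,
        stack_distance_A=(5.79,) * n_frames,
        stack_angle_deg=(52.0,) * n_frames,
        seed=seed,
    )


_RING_TEMPLATE = 1.4 * np.array(
    [
        [math.cos(a), math.sin(a), 0.0]
        for a in (2 * math.pi * k / 6 for k in range(6))
    ]
)

_MIN_ATOM_SEPARATION_A = 0.8


def gen_trajectory(
    recipe: TrajectoryRecipe, rng: np.random.Generator | None = None
) -> tuple[str, dict]:
    """Generate multi-model PDB text plus its ground-truth report.

    The report dict carries exactly what the analytics should recover:
    ``hbond_occupancy_pct``, ``stacked_fraction`` (under the default
    5.0 A / 30 deg thresholds), ``violation_pct``, the restraint radii, and
    the probe-pair distance sample mean/SD.
    """
    rng = np.random.default_rng(recipe.seed) if rng is None else rng
    n = recipe.n_frames
    frames = []
    pair_distances = []
    r_i_A = recipe.restraint_r_i_nm * 10.0
    r1_A = r_i_A + 3.0  # r_i + 0.30 nm in Angstrom
    for f in range(n):
        atoms = []  # (name, resname, resid, element, xyz)
        # hydrogen-bond group at the origin
        atoms.append(("N", "DON", 1, "N", np.array([0.0, 0.0, 0.0])))
        atoms.append(("H", "DON", 1, "H", np.array([1.0, 0.0, 0.0])))
        if recipe.hbond_on[f]:
            o_xyz = np.array([2.9, 0.0, 0.0])  # collinear, inside both cutoffs
        elif recipe.hbond_off_mode == "distance":
            o_xyz = np.array([3.5, 0.0, 0.0])  # distance fail
        else:
            # 2.8 A from N but 45 deg off the N-H axis: angle fail
            theta = math.radians(45.0)
            o_xyz = 2.8 * np.array([math.cos(theta), math.sin(theta), 0.0])
        atoms.append(("O", "ACC", 2, "O", o_xyz))
        # ring pair around (0, 50, 0)
        base = np.array([0.0, 50.0, 0.0])
        for i, xyz in enumerate(_RING_TEMPLATE):
            atoms.append((f"C{i + 1}", "RGA", 3, "C", base + xyz))
        theta = math.radians(recipe.stack_angle_deg[f])
        rot_x = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(theta), -math.sin(theta)],
                [0.0, math.sin(theta), math.cos(theta)],
            ]
        )
        offset = base + np.array([0.0, 0.0, recipe.stack_distance_A[f]])
        for i, xyz in enumerate(_RING_TEMPLATE):
            atoms.append((f"C{i + 1}", "RGB", 4, "C", offset + rot_x @ xyz))
        # restraint pair around (50, 0, 0)
        r_A = r1_A + 2.0 if recipe.violating[f] else r_i_A
        atoms.append(("C1", "RSA", 5, "C", np.array([50.0, 0.0, 0.0])))
        atoms.append(("C1", "RSB", 6, "C", np.array([50.0 + r_A, 0.0, 0.0])))
        # Gaussian probe pair around (0, 0, 50)
        d = max(rng.normal(recipe.pair_mean_A, recipe.pair_sd_A), _MIN_ATOM_SEPARATION_A)
        pair_distances.append(d)
        atoms.append(("C1", "PRA", 7, "C", np.array([0.0, 0.0, 50.0])))
        atoms.append(("C1", "PRB", 8, "C", np.array([d, 0.0, 50.0])))
        _check_feasible(atoms, f)
        frames.append(atoms)

    pdb_text = _write_multi_model_pdb(frames)
    pair = np.round(np.asarray(pair_distances), 3)  # PDB precision
    truth = {
        "hbond_occupancy_pct": 100.0 * sum(recipe.hbond_on) / n,
        "stacked_fraction": sum(
            1
            for d, a in zip(recipe.stack_distance_A, recipe.stack_angle_deg)
            if d <= 5.0 and min(a % 180.0, 180.0 - a % 180.0) <= 30.0
        )
        / n,
        "violation_pct": 100.0 * sum(recipe.violating) / n,
        "restraint_r0_nm": recipe.restraint_r_i_nm - 0.30,
        "restraint_r1_nm": recipe.restraint_r_i_nm + 0.30,
        "pair_mean_A": float(pair.mean()),
        "pair_sd_A": float(pair.std()),
        "hbond_donor": "1:N",
        "hbond_acceptor": "2:O",
        "ring_a": [f"3:C{i + 1}" for i in range(6)],
        "ring_b": [f"4:C{i + 1}" for i in range(6)],
        "restraint_pair": ("5:C1", "6:C1"),
        "probe_pair": ("7:C1", "8:C1"),
    }
    return pdb_text, truth


def _check_feasible(atoms, frame: int) -> None:
    xyz = np.stack([a[4] for a in atoms])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    # bonded N-H (1.0 A) is the one legitimate short contact
    mask = np.ones_like(dist, dtype=bool)
    mask[0, 1] = mask[1, 0] = False
    if np.any(dist[mask] < _MIN_ATOM_SEPARATION_A):
        raise RecipeError(f"frame {frame}: atoms overlap closer than 0.8 A")


def _write_multi_model_pdb(frames) -> str:
    lines = []
    for f, atoms in enumerate(frames, start=1):
        lines.append(f"MODEL     {f:4d}")
        for serial, (name, resname, resid, element, xyz) in enumerate(atoms, start=1):
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:>3s} A{resid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
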