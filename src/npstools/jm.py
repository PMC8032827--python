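"""Classification of psoralen-EM DNA molecules into replication-intermediate
and joint-molecule (JM) categories from measured branch lengths.

Under the spreading conditions used for EM of replication intermediates,
180 nm of DNA filament corresponds to 500 bp, giving the default calibration
of ~2.778 bp/nm.

Each molecule is recorded as a junction count plus the branch lengths at the
junction (nm). The taxonomy is decided by ordered geometric rules that
codify the field's verbal criteria, with one tolerance knob ``rel_tol``
(default 5%) for calling two lengths "equal":

1. no junction, two branches — a linear molecule (excluded from JM tallies);
2. one three-branch junction — a replication fork;
3. two junctions, four branches each — a double Holliday Junction (dHJ;
   keyed on junction count alone, as no length criterion exists for dHJs);
   two junctions of three branches each — a replication bubble;
4. one four-way junction with an equal pair of branches (the sister
   daughter arms) and the shortest remaining branch (the regressed arm) no
   longer than the daughters — a reversed fork;
5. one four-way junction where some pairing of the branches into two
   opposite pairs gives equal sums — two through-going filaments of the
   same size — and rule 4 fails: a hemicatenane;
6. anything else with one four-way junction — unclassified.

Rules use only ratios of lengths, so classification is invariant to branch
order and to uniform rescaling (and hence to the nm→bp calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CalibrationConstant",
    "JMRecord",
    "nm_to_bp",
    "classify_jm",
    "tabulate_frequencies",
    "JM_CATEGORIES",
]

#: Categories reported in frequency tables, in display order.
JM_CATEGORIES = ("fork", "bubble", "reversed_fork", "dHJ", "hemicatenane", "unclassified")


@dataclass(frozen=True)
class CalibrationConstant:
    """EM length calibration; default 500 bp per 180 nm of filament."""

    bp_per_nm: float = 500.0 / 180.0

    def __post_init__(self) -> None:
        if not self.bp_per_nm > 0:
            raise ValueError("bp_per_nm must be strictly positive")


def nm_to_bp(length_nm: float, cal: CalibrationConstant = CalibrationConstant()) -> float:
    """Convert a filament length in nm to bp via the EM calibration."""
    if length_nm < 0:
        raise ValueError(f"negative length {length_nm} nm")
    return length_nm * cal.bp_per_nm


@dataclass(frozen=True)
class JMRecord:
    """One EM molecule: junction count, branches per junction, branch lengths.

    ``branch_lengths_nm`` are the lengths measured at the junction of a
    single-junction molecule (3 for a fork, 4 for a four-way junction).
    For two-junction molecules classification keys on the junction geometry
    (``n_junctions``, ``n_branches``) alone, so lengths may be empty.
    """

    molecule_id: str
    genotype: str
    n_junctions: int
    branch_lengths_nm: tuple[float, ...] = ()
    n_branches: int | None = None
    true_category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch_lengths_nm", tuple(float(x) for x in self.branch_lengths_nm))
        if self.n_junctions < 0:
            raise ValueError("n_junctions must be >= 0")
        if any(x <= 0 for x in self.branch_lengths_nm):
            raise ValueError(f"molecule {self.molecule_id}: branch lengths must be > 0")
        if self.n_branches is None:
            object.__setattr__(self, "n_branches", len(self.branch_lengths_nm))


def _close(x: float, y: float, rel_tol: float) -> bool:
    return abs(x - y) <= rel_tol * max(x, y)


def _is_reversed_fork(lengths: Sequence[float], rel_tol: float) -> bool:
    # some equal pair (daughter arms) whose complement's shortest branch
    # (the regressed arm) is <= the daughter length
    for i, j in combinations(range(4), 2):
        if _close(lengths[i], lengths[j], rel_tol):
            rest = [lengths[k] for k in range(4) if k not in (i, j)]
            daughters = min(lengths[i], lengths[j])
            if min(rest) <= daughters * (1 + rel_tol):
                return True
    return False


def _is_hemicatenane(lengths: Sequence[float], rel_tol: float) -> bool:
    # some pairing into two opposite pairs with equal sums: two intact
    # duplexes of the same size crossing at the junction
    a, b, c, d = lengths
    pairings = ((a + b, c + d), (a + c, b + d), (a + d, b + c))
    return any(_close(s1, s2, rel_tol) for s1, s2 in pairings)


def classify_jm(record: JMRecord, *, rel_tol: float = 0.05) -> str:
    """Assign one molecule to the taxonomy; deterministic, rule-ordered.

    Returns one of ``linear``, ``fork``, ``bubble``, ``dHJ``,
    ``reversed_fork``, ``hemicatenane`` or ``unclassified``. ``linear``
    molecules are not replication intermediates and are excluded from JM
    frequency tables.
    """
    nj, nb = record.n_junctions, record.n_branches
    if nj == 0:
        if nb == 2:
            return "linear"
        raise ValueError(
            f"molecule {record.molecule_id}: {nb} branches inconsistent with 0 junctions"
        )
    if nj == 1:
        if nb == 3:
            return "fork"
        if nb == 4:
            lengths = record.branch_lengths_nm
            if len(lengths) != 4:
                raise ValueError(
                    f"molecule {record.molecule_id}: four-way junction needs 4 branch lengths"
                )
            if _is_reversed_fork(lengths, rel_tol):
                return "reversed_fork"
            if _is_hemicatenane(lengths, rel_tol):
                return "hemicatenane"
            return "unclassified"
        raise ValueError(
            f"molecule {record.molecule_id}: {nb} branches inconsistent with 1 junction"
        )
    if nj == 2:
        if nb == 4:
            return "dHJ"
        if nb == 3:
            return "bubble"
        raise ValueError(
            f"molecule {record.molecule_id}: {nb} branches inconsistent with 2 junctions"
        )
    raise ValueError(f"molecule {record.molecule_id}: unsupported junction count {nj}")


def tabulate_frequencies(
    records: Iterable[JMRecord], *, rel_tol: float = 0.05
) -> pd.DataFrame:
    """Per-genotype frequency table of intermediate categories.

    Rows are genotypes; columns are the number of molecules analysed (``n``,
    linear molecules excluded) and the percentage per category. Percentages
    per genotype sum to 100.
    """
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        cat = classify_jm(rec, rel_tol=rel_tol)
        if cat == "linear":
            continue
        geno = rows.setdefault(rec.genotype, {c: 0 for c in JM_CATEGORIES})
        geno[cat] += 1
    if not rows:
        raise ValueError("no classifiable molecules")
    out = []
    for genotype, counts in rows.items():
        n = sum(counts.values())
        row: dict[str, object] = {"genotype": genotype, "n": n}
        for cat in JM_CATEGORIES:
            row[f"{cat}_pct"] = 100.0 * counts[cat] / n
        out.append(row)
    return pd.DataFrame(out).set_index("genotype")
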