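"""Master matrices and the fitness/projection algebra built on them.

The simulator tracks one haploid biallelic locus in each of three players:
host (alleles H1, H2), defensive symbiont (alleles S1, S2, or absent) and
parasite (genotypes P1, P2).  A host genotype combined with its symbiont
state is an *association*; symbiont-free hosts count as associations too,
giving six associations in a fixed canonical order.

All genetics is subsumed in a 6x2 *master matrix* M whose entry
``m[a][p]`` in [0, 1] is the degree of resistance of association ``a``
against parasite genotype ``p``.  From M and three scalar parameters --
the maximal selection strengths s_H and s_P and the symbiont cost c --
the host and parasite fitness matrices are derived::

    wH[(i,s)][p] = (1 - s_H * (1 - m[(i,s)][p])) * (1 - c * 1[s != none])
    wP[p][(i,s)] = 1 - s_P * m[(i,s)][p]

so a fully resistant symbiont-free host has fitness 1, and host and
parasite fitnesses are fully anti-correlated in m.

Pairwise 2x2 interaction matrices (host-parasite HP, symbiont-parasite SP,
host-symbiont HS) are obtained by averaging out the third species; they are
the objects scored by :mod:`symcoev.specificity`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "ASSOCIATION_LABELS",
    "PARASITE_LABELS",
    "SYMBIONT_STATES",
    "MasterMatrix",
    "FitnessPair",
    "PairwiseMatrix",
    "derive_host_fitness",
    "derive_parasite_fitness",
    "derive_fitness_pair",
    "project",
    "make_ma_master",
    "make_gfg_master",
    "make_canonical_square",
]

#: Canonical association ordering used everywhere in the package.
ASSOCIATION_LABELS: tuple[str, ...] = (
    "H1:none", "H1:S1", "H1:S2", "H2:none", "H2:S1", "H2:S2",
)
PARASITE_LABELS: tuple[str, ...] = ("P1", "P2")
SYMBIONT_STATES: tuple[str, ...] = ("none", "S1", "S2")

# Row indices of the canonical ordering, grouped by host allele:
# host i occupies rows 3*i + {0 (no symbiont), 1 (S1), 2 (S2)}.
_FREE_ROWS = np.array([0, 3])      # H1:none, H2:none
_S1_ROWS = np.array([1, 4])
_S2_ROWS = np.array([2, 5])


def _check_unit_interval(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"parameter {name}={value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class MasterMatrix:
    """6x2 resistance matrix of every association against every parasite.

    Parameters
    ----------
    entries
        Array-like of shape (6, 2) with values in [0, 1]; rows follow
        :data:`ASSOCIATION_LABELS`, columns :data:`PARASITE_LABELS`.
    protective
        If True (default), validation additionally requires that carrying a
        symbiont never lowers resistance below the symbiont-free baseline:
        ``m[(i,s)][p] >= m[(i,none)][p]`` for every host allele i, symbiont
        allele s and parasite p.
    """

    entries: np.ndarray
    protective: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.shape != (6, 2):
            raise ValueError(f"master matrix must be 6x2, got {arr.shape}")
        if not np.all((arr >= 0.0) & (arr <= 1.0)):
            raise ValueError("master matrix entries must lie in [0, 1]")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "entries", arr)
        if self.protective and not self.satisfies_protection():
            raise ValueError(
                "matrix flagged protective but a symbiont row falls below "
                "its symbiont-free baseline"
            )

    def satisfies_protection(self) -> bool:
        """True iff symbionts never impair innate host resistance."""
        m = self.entries
        free = m[_FREE_ROWS]
        return bool(np.all(m[_S1_ROWS] >= free) and np.all(m[_S2_ROWS] >= free))

    # --- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "labels_assoc": list(ASSOCIATION_LABELS),
            "labels_par": list(PARASITE_LABELS),
            "entries": self.entries.tolist(),
            "protective": bool(self.protective),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MasterMatrix":
        if tuple(d.get("labels_assoc", ASSOCIATION_LABELS)) != ASSOCIATION_LABELS:
            raise ValueError("association labels do not match canonical ordering")
        if tuple(d.get("labels_par", PARASITE_LABELS)) != PARASITE_LABELS:
            raise ValueError("parasite labels do not match canonical ordering")
        return cls(np.array(d["entries"], dtype=float),
                   protective=bool(d.get("protective", True)))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "MasterMatrix":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["association", *PARASITE_LABELS])
            for label, row in zip(ASSOCIATION_LABELS, self.entries):
                writer.writerow([label, *(repr(float(v)) for v in row)])

    @classmethod
    def from_csv(cls, path: str | Path, protective: bool = True) -> "MasterMatrix":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        header, body = rows[0], rows[1:]
        if tuple(header[1:]) != PARASITE_LABELS or len(body) != 6:
            raise ValueError("matrix CSV does not match the canonical 6x2 layout")
        if tuple(r[0] for r in body) != ASSOCIATION_LABELS:
            raise ValueError("association labels do not match canonical ordering")
        entries = np.array([[float(v) for v in r[1:]] for r in body])
        return cls(entries, protective=protective)


def derive_host_fitness(m: MasterMatrix | np.ndarray, s_H: float, c: float) -> np.ndarray:
    """Host fitness matrix wH (6x2) from a master matrix.

    ``wH[(i,s)][p] = (1 - s_H*(1 - m[(i,s)][p])) * (1 - c)`` for
    symbiont-bearing rows, without the cost factor for symbiont-free rows.
    With full resistance (m=1) a symbiont-free host has fitness exactly 1;
    with s_H=1 a fully susceptible host can be driven to fitness 0.
    """
    s_H = _check_unit_interval(s_H, "s_H")
    c = _check_unit_interval(c, "c")
    entries = m.entries if isinstance(m, MasterMatrix) else np.asarray(m, dtype=float)
    wH = 1.0 - s_H * (1.0 - entries)
    cost = np.ones((6, 1))
    cost[_S1_ROWS] = 1.0 - c
    cost[_S2_ROWS] = 1.0 - c
    return wH * cost


def derive_parasite_fitness(m: MasterMatrix | np.ndarray, s_P: float) -> np.ndarray:
    """Parasite fitness matrix wP (2x6): ``wP[p][a] = 1 - s_P * m[a][p]``."""
    s_P = _check_unit_interval(s_P, "s_P")
    entries = m.entries if isinstance(m, MasterMatrix) else np.asarray(m, dtype=float)
    return (1.0 - s_P * entries).T


@dataclass(frozen=True)
class FitnessPair:
    """Host (6x2) and parasite (2x6) fitness matrices plus their parameters."""

    host_fitness: np.ndarray
    parasite_fitness: np.ndarray
    s_H: float
    s_P: float
    c: float

    def __post_init__(self) -> None:
        wH = np.asarray(self.host_fitness, dtype=float)
        wP = np.asarray(self.parasite_fitness, dtype=float)
        if wH.shape != (6, 2) or wP.shape != (2, 6):
            raise ValueError("fitness matrices must be 6x2 (host) and 2x6 (parasite)")
        if not (np.all((wH >= 0) & (wH <= 1)) and np.all((wP >= 0) & (wP <= 1))):
            raise ValueError("fitness entries must lie in [0, 1]")
        object.__setattr__(self, "host_fitness", wH)
        object.__setattr__(self, "parasite_fitness", wP)


def derive_fitness_pair(m: MasterMatrix, s_H: float, s_P: float, c: float) -> FitnessPair:
    return FitnessPair(
        host_fitness=derive_host_fitness(m, s_H, c),
        parasite_fitness=derive_parasite_fitness(m, s_P),
        s_H=float(s_H), s_P=float(s_P), c=float(c),
    )


@dataclass(frozen=True)
class PairwiseMatrix:
    """2x2 projection of a master matrix (kind HP, SP or HS)."""

    kind: str
    entries: np.ndarray
    row_labels: tuple[str, str] = field(default=("", ""))
    col_labels: tuple[str, str] = field(default=("", ""))

    def __post_init__(self) -> None:
        if self.kind not in ("HP", "SP", "HS"):
            raise ValueError(f"unknown projection kind {self.kind!r}")
        arr = np.asarray(self.entries, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError("pairwise matrix must be 2x2")
        object.__setattr__(self, "entries", arr)


def project(m: MasterMatrix | np.ndarray, kind: str,
            include_symbiont_free: bool = True) -> PairwiseMatrix:
    """Project a master matrix onto a 2x2 pairwise interaction matrix.

    HP averages out the symbiont state (by default over all three states,
    symbiont-free included, since symbiont-free hosts are associations in
    their own right; pass ``include_symbiont_free=False`` for the two-state
    variant), SP averages out the host allele, HS averages out the parasite.
    """
    entries = m.entries if isinstance(m, MasterMatrix) else np.asarray(m, dtype=float)
    by_host = entries.reshape(2, 3, 2)  # (host, symbiont state, parasite)
    if kind == "HP":
        states = slice(None) if include_symbiont_free else slice(1, None)
        q = by_host[:, states, :].mean(axis=1)
        rows, cols = ("H1", "H2"), PARASITE_LABELS
    elif kind == "SP":
        q = by_host[:, 1:, :].mean(axis=0)
        rows, cols = ("S1", "S2"), PARASITE_LABELS
    elif kind == "HS":
        q = by_host[:, 1:, :].mean(axis=2)
        rows, cols = ("H1", "H2"), ("S1", "S2")
    else:
        raise ValueError(f"unknown projection kind {kind!r}")
    return PairwiseMatrix(kind=kind, entries=q, row_labels=rows, col_labels=cols)


def _symbiont_augmented(innate: np.ndarray, delta: float) -> MasterMatrix:
    """Master matrix from a 2x2 innate resistance pattern plus specialised
    symbiont protection: symbiont s grants resistance ``delta`` against
    parasite s; combined resistance is max(innate, granted)."""
    delta = _check_unit_interval(delta, "delta")
    grant = np.diag([delta, delta])
    rows = []
    for i in range(2):
        rows.append(innate[i])                          # no symbiont
        rows.append(np.maximum(innate[i], grant[0]))    # S1
        rows.append(np.maximum(innate[i], grant[1]))    # S2
    return MasterMatrix(np.array(rows), protective=True)


def make_ma_master(delta: float) -> MasterMatrix:
    """Matching-alleles master matrix with specialised symbiont protection.

    Innately, host i fully resists parasite i and is fully susceptible to
    the other; symbiont s adds resistance ``delta`` against parasite s where
    innate resistance is absent.
    """
    return _symbiont_augmented(np.eye(2), delta)


def make_gfg_master(delta: float) -> MasterMatrix:
    """Gene-for-gene master matrix with specialised symbiont protection.

    Innately, the resistant host H1 resists the avirulent parasite P1 only;
    H2 resists nothing.  Symbiont protection as in :func:`make_ma_master`.
    """
    return _symbiont_augmented(np.array([[1.0, 0.0], [0.0, 0.0]]), delta)


def make_canonical_square(kind: str, n: int) -> np.ndarray:
    """Canonical n x n host-parasite resistance matrix (no symbionts).

    MA is the identity pattern (host i resists parasite i only).  IMA is the
    mirror image of MA (columns reversed).  GFG enumerates hosts and
    parasites as allele subsets of a multi-locus resistance/virulence
    system: hosts ordered most-resistant first, parasites least-virulent
    first, with resistance 1 iff some host resistance allele is uncountered
    by a parasite virulence allele (so GFG(2) = [[1,0],[0,0]]).
    """
    if n < 2:
        raise ValueError(f"canonical matrices need n >= 2, got {n}")
    if kind == "MA":
        return np.eye(n)
    if kind == "IMA":
        return np.fliplr(np.eye(n))
    if kind == "GFG":
        n_loci = max(1, int(np.ceil(np.log2(n))))
        subsets = sorted(range(2 ** n_loci),
                         key=lambda s: (bin(s).count("1"), s))[:n]
        hosts = sorted(subsets, key=lambda s: -bin(s).count("1"))
        parasites = sorted(subsets, key=lambda s: bin(s).count("1"))
        return np.array([[1.0 if (h & ~p) else 0.0 for p in parasites]
                         for h in hosts])
    raise ValueError(f"unknown canonical kind {kind!r}")
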