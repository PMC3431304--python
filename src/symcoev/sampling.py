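"""Random master-matrix generation, stratified over specificity bins.

Two entry samplers are provided: independent uniform draws on [0,1]
(i.u.d.) and a symmetric bimodal density with modes at 0 and 1 that yields
the polarised entries characteristic of high-specificity matrices.  The
bimodal density is a mixture: with weight 0.9 uniform on the mode
intervals [0, 0.1] and [0.9, 1], with weight 0.1 uniform on [0, 1] (so the
density is 4.6 on the mode intervals and 0.1 between them).  The uniform
floor is essential: without full support, symbiont-parasite projections —
averages of two entries — can never produce specificity scores inside
(0.55, 0.8), leaving the [0.7, 0.8) stratification bin unreachable.  Every matrix is subjected to
whole-matrix rejection until the protection constraint holds (symbionts
never impair innate resistance); for i.u.d. entries the per-cell chance
that both symbiont entries beat the symbiont-free one is 1/3, so a 6x2
matrix is accepted with probability (1/3)^4 = 1/81.

:func:`build_ensemble` fills ten specificity bins of width 0.1 with a
fixed number of matrices each: bins up to [0.6, 0.7) from the i.u.d.
sampler, the top three bins from the bimodal sampler, mirroring the fact
that i.u.d. sampling produces no high-specificity matrices in reasonable
time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .matrices import MasterMatrix, project
from .specificity import specificity_2x2_batch

__all__ = [
    "MatrixRecord",
    "MatrixEnsemble",
    "sample_iud",
    "sample_bimodal",
    "build_ensemble",
    "IUD_ACCEPTANCE_PROBABILITY",
]

#: Exact acceptance probability of the protection constraint under i.u.d.
IUD_ACCEPTANCE_PROBABILITY = (1.0 / 3.0) ** 4

#: Mixture weight of the polarised component of the bimodal density.
BIMODAL_MODE_WEIGHT = 0.9

_BIN_EDGES = np.round(np.arange(0.0, 1.1, 0.1), 10)
#: Bins filled by the i.u.d. sampler; the rest use the bimodal sampler.
IUD_BINS = range(0, 7)

_BATCH = 100_000


def _protective_mask(entries: np.ndarray) -> np.ndarray:
    """entries: (B, 6, 2) in canonical order -> (B,) acceptance mask."""
    by_host = entries.reshape(-1, 2, 3, 2)
    free = by_host[:, :, :1, :]
    return np.all(by_host[:, :, 1:, :] >= free, axis=(1, 2, 3))


def _draw_entries(rng: np.random.Generator, n: int, sampler: str) -> np.ndarray:
    if sampler == "iud":
        return rng.uniform(size=(n, 6, 2))
    if sampler == "bimodal":
        y = rng.uniform(0.0, 0.2, size=(n, 6, 2))
        polar = np.where(y <= 0.1, y, y + 0.8)
        floor = rng.uniform(size=(n, 6, 2))
        pick = rng.uniform(size=(n, 6, 2)) < BIMODAL_MODE_WEIGHT
        return np.where(pick, polar, floor)
    raise ValueError(f"unknown sampler {sampler!r}")


def _draw_accepted(rng: np.random.Generator, n: int, sampler: str) -> np.ndarray:
    """Draw n protection-constrained matrices by whole-matrix rejection."""
    out = []
    have = 0
    while have < n:
        raw = _draw_entries(rng, _BATCH, sampler)
        acc = raw[_protective_mask(raw)]
        out.append(acc)
        have += len(acc)
    return np.concatenate(out)[:n]


def sample_iud(rng: np.random.Generator) -> MasterMatrix:
    """One master matrix with i.u.d. entries, rejected until protective."""
    return MasterMatrix(_draw_accepted(rng, 1, "iud")[0])


def sample_bimodal(rng: np.random.Generator) -> MasterMatrix:
    """One master matrix with symmetric-bimodal entries (modes 0 and 1),
    rejected until protective."""
    return MasterMatrix(_draw_accepted(rng, 1, "bimodal")[0])


def _projection_batch(entries: np.ndarray, kind: str) -> np.ndarray:
    """(B, 6, 2) -> (B, 2, 2) pairwise projections, vectorised."""
    by_host = entries.reshape(-1, 2, 3, 2)
    if kind == "HP":
        return by_host.mean(axis=2)
    if kind == "SP":
        return by_host[:, :, 1:, :].mean(axis=1)
    if kind == "HS":
        return by_host[:, :, 1:, :].mean(axis=3)
    raise ValueError(f"unknown projection kind {kind!r}")


def specificity_bin(score: float) -> int:
    """Sampling bin of a specificity score: [0,0.1), ..., [0.9,1.0]."""
    return min(int(score * 10), 9)


@dataclass(frozen=True)
class MatrixRecord:
    id: str
    sampler: str
    entries: np.ndarray
    S_HP: float
    S_SP: float
    S_HS: float
    bin: int

    def master(self) -> MasterMatrix:
        return MasterMatrix(self.entries)


@dataclass
class MatrixEnsemble:
    """A stratified collection of protection-constrained master matrices."""

    target_kind: str
    per_bin: int
    rng_seed: Optional[int]
    matrices: list[MatrixRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    def scores(self, kind: Optional[str] = None) -> np.ndarray:
        kind = kind or self.target_kind
        return np.array([getattr(r, f"S_{kind}") for r in self.matrices])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_kind": self.target_kind,
            "per_bin": self.per_bin,
            "rng_seed": self.rng_seed,
            "matrices": [
                {"id": r.id, "sampler": r.sampler, "bin": r.bin,
                 "S_HP": r.S_HP, "S_SP": r.S_SP, "S_HS": r.S_HS,
                 "entries": r.entries.tolist()}
                for r in self.matrices
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MatrixEnsemble":
        d = json.loads(Path(path).read_text())
        matrices = [
            MatrixRecord(id=r["id"], sampler=r["sampler"], bin=int(r["bin"]),
                         S_HP=float(r["S_HP"]), S_SP=float(r["S_SP"]),
                         S_HS=float(r["S_HS"]),
                         entries=np.array(r["entries"], dtype=float))
            for r in d["matrices"]
        ]
        return cls(target_kind=d["target_kind"], per_bin=int(d["per_bin"]),
                   rng_seed=d.get("rng_seed"), matrices=matrices)


def build_ensemble(target_kind: str, per_bin: int,
                   rng: np.random.Generator | int,
                   draw_budget: int = 100_000_000) -> MatrixEnsemble:
    """Fill ten specificity bins with ``per_bin`` matrices each.

    Bins [0, 0.1) through [0.6, 0.7) are filled with i.u.d.-sampled
    matrices, the top three with bimodal-sampled ones.  The bin of a matrix
    is determined by the specificity of its ``target_kind`` (HP or SP)
    projection.  Draws are capped at ``draw_budget`` per sampler phase; an
    unreachable bin raises rather than hanging.
    """
    if target_kind not in ("HP", "SP"):
        raise ValueError("ensembles are stratified on HP or SP specificity")
    if per_bin < 1:
        raise ValueError("per_bin must be at least 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    needed = {b: per_bin for b in range(10)}
    kept: dict[int, list[np.ndarray]] = {b: [] for b in range(10)}
    samplers = (("iud", set(IUD_BINS)), ("bimodal", {7, 8, 9}))
    for sampler, bins in samplers:
        drawn = 0
        while any(needed[b] for b in bins):
            if drawn >= draw_budget:
                open_bins = [b for b in bins if needed[b]]
                raise RuntimeError(
                    f"draw budget {draw_budget} exhausted with bins "
                    f"{open_bins} still unfilled ({sampler} sampler)")
            raw = _draw_entries(rng, _BATCH, sampler)
            drawn += _BATCH
            acc = raw[_protective_mask(raw)]
            if not len(acc):
                continue
            scores = specificity_2x2_batch(_projection_batch(acc, target_kind))
            assigned = np.minimum((scores * 10).astype(int), 9)
            for b in bins:
                if needed[b]:
                    hits = acc[assigned == b]
                    take = hits[: needed[b]]
                    kept[b].extend(take)
                    needed[b] -= len(take)
    records = []
    idx = 0
    for b in range(10):
        sampler = "iud" if b in IUD_BINS else "bimodal"
        for entries in kept[b]:
            hp = float(specificity_2x2_batch(_projection_batch(entries[None], "HP"))[0])
            sp = float(specificity_2x2_batch(_projection_batch(entries[None], "SP"))[0])
            hs = float(specificity_2x2_batch(_projection_batch(entries[None], "HS"))[0])
            records.append(MatrixRecord(
                id=f"m{idx:05d}", sampler=sampler, entries=entries,
                S_HP=hp, S_SP=sp, S_HS=hs, bin=b))
            idx += 1
    return MatrixEnsemble(target_kind=target_kind, per_bin=per_bin,
                          rng_seed=seed, matrices=records)
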