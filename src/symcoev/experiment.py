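"""Study orchestration: parameter grids, ensemble sweeps, binned summaries.

The full design crosses a master-matrix ensemble with a parameter grid of
three values each for s_H, s_P and c (27 fitness pairs per matrix) and two
values each for the vertical-transmission fidelity v and the horizontal
rate tau (108 models per matrix).  Every model is simulated under ten
random initialisations plus one equal-frequency run, classified, and the
per-model outcomes are aggregated into eleven specificity bins (bin 0 =
exactly non-specific matrices, bins 1-10 equally spaced over (0, 1]).

The printed sources fix the 3x3x3x2x2 grid structure; the default values
here are reconstructions chosen to span weak-to-maximal selection and
cheap-to-prohibitive symbiont cost, with an "aphid-wasp" preset loosely
matching Hamiltonella defensa-protected aphid systems (strong selection on
hosts, moderate on parasitoids, cheap symbionts, near-perfect maternal
transmission, rare horizontal transfer).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .matrices import (ASSOCIATION_LABELS, MasterMatrix, derive_fitness_pair,
                       make_gfg_master, make_ma_master)
from .dynamics import SimParams, equal_state, random_state, simulate_batch
from .metrics import (LOSS_THRESHOLD, outcome_tuples, outcomes_from_batch)
from .sampling import MatrixEnsemble, MatrixRecord

__all__ = [
    "ParameterGrid",
    "APHID_WASP_PRESET",
    "run_grid",
    "summarize_by_bin",
    "analysis_bin",
    "run_canonical_study",
    "write_results",
    "read_results",
]

#: Parameters loosely matching defensive-symbiont aphid-parasitoid systems.
APHID_WASP_PRESET = dict(s_H=1.0, s_P=0.5, c=0.05, v=0.99, tau=0.01)

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ParameterGrid:
    """The 3x3x3 fitness-parameter grid crossed with 2x2 transmission values."""

    s_H: tuple[float, ...] = (0.2, 0.5, 1.0)
    s_P: tuple[float, ...] = (0.2, 0.5, 1.0)
    c: tuple[float, ...] = (0.05, 0.2, 0.5)
    v: tuple[float, ...] = (0.99, 1.0)
    tau: tuple[float, ...] = (0.0, 0.01)

    @property
    def n_fitness_combos(self) -> int:
        return len(self.s_H) * len(self.s_P) * len(self.c)

    @property
    def n_combos(self) -> int:
        return self.n_fitness_combos * len(self.v) * len(self.tau)

    def combos(self, n_generations: int = 20000, burn_in: int = 10000
               ) -> list[SimParams]:
        """All parameter combinations in canonical (product) order."""
        return [
            SimParams(s_H=sh, s_P=sp, c=cc, v=vv, tau=tt,
                      n_generations=n_generations, burn_in=burn_in)
            for sh, sp, cc, vv, tt in itertools.product(
                self.s_H, self.s_P, self.c, self.v, self.tau)
        ]

    def nontrivial_combos(self, **kw) -> list[SimParams]:
        return [p for p in self.combos(**kw) if p.c < p.s_H]

    def representative_nontrivial(self, k: int = 12, **kw) -> list[SimParams]:
        """A deterministic stratified subset of the non-trivial combos.

        Strides through the combos ordered transmission-major (tau, v
        slowest), so the subset balances both transmission regimes and
        spans the fitness-parameter grid."""
        combos = sorted(self.nontrivial_combos(**kw),
                        key=lambda p: (p.tau, p.v, p.c, p.s_P, p.s_H))
        if k >= len(combos):
            return combos
        idx = np.unique(np.round(np.linspace(0, len(combos) - 1, k)).astype(int))
        return [combos[i] for i in idx]


def _run_seed(base_seed: int, matrix_index: int, combo_index: int,
              run_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([base_seed, matrix_index, combo_index, run_index]))


def _stack_runs(masters: Sequence[MasterMatrix], combos: Sequence[SimParams],
                n_random_inits: int, seed: int):
    """Build stacked (R, ...) arrays for matrices x combos x (random+equal) runs."""
    n_runs = n_random_inits + 1
    R = len(masters) * len(combos) * n_runs
    wH = np.empty((R, 6, 2))
    wP = np.empty((R, 2, 6))
    v = np.empty(R)
    tau = np.empty(R)
    f0 = np.empty((R, 6))
    q0 = np.empty((R, 2))
    index = []
    eq = equal_state()
    r = 0
    for mi, master in enumerate(masters):
        fits = [derive_fitness_pair(master, p.s_H, p.s_P, p.c) for p in combos]
        for ci, (p, fit) in enumerate(zip(combos, fits)):
            for run in range(n_runs):
                wH[r] = fit.host_fitness
                wP[r] = fit.parasite_fitness
                v[r], tau[r] = p.v, p.tau
                if run < n_random_inits:
                    state = random_state(_run_seed(seed, mi, ci, run))
                else:
                    state = eq
                f0[r], q0[r] = state.f, state.q
                index.append((mi, ci, run))
                r += 1
    return wH, wP, v, tau, f0, q0, index


def run_grid(ensemble: MatrixEnsemble | Sequence[MasterMatrix],
             grid: ParameterGrid | Sequence[SimParams] = ParameterGrid(),
             seed: int = 0, n_random_inits: int = 10,
             n_generations: int = 20000, burn_in: int = 10000,
             include_trivial: bool = True,
             checkpoint_dir: Optional[str | Path] = None,
             chunk_size: int = 200) -> pd.DataFrame:
    """Simulate and classify every (master matrix, parameter combo) model.

    Returns one row per model with its discrete outcome (from the
    equal-frequency run), its ambiguity across the 11 runs, and the
    matrix's specificity scores.  Trivial combos (c >= s_H) are flagged;
    by default they are kept in the table (downstream summaries exclude
    them).  With ``checkpoint_dir`` set, finished matrix-chunks are written
    to disk and complete chunks are reused on re-run; corrupted chunk files
    are refused rather than merged.
    """
    if isinstance(ensemble, MatrixEnsemble):
        records: list[MatrixRecord] = list(ensemble.matrices)
        masters = [r.master() for r in records]
    else:
        masters = list(ensemble)
        records = None
    combos = (grid.combos(n_generations=n_generations, burn_in=burn_in)
              if isinstance(grid, ParameterGrid) else list(grid))
    if not include_trivial:
        combos = [p for p in combos if p.c < p.s_H]

    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    frames = []
    # chunk over matrices so memory stays bounded and checkpoints are useful
    per_chunk = max(1, chunk_size // max(1, len(combos) // 10))
    for start in range(0, len(masters), per_chunk):
        stop = min(start + per_chunk, len(masters))
        if ckpt:
            path = ckpt / f"chunk_{start:06d}_{stop:06d}.csv"
            if path.exists():
                try:
                    frames.append(read_results(path))
                    continue
                except Exception as exc:
                    raise RuntimeError(
                        f"refusing to merge corrupted checkpoint {path}: {exc}"
                    ) from exc
        frame = _grid_chunk(masters[start:stop], records, start, combos,
                            seed, n_random_inits)
        if ckpt:
            write_results(frame, path, seed=seed)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _grid_chunk(masters, records, offset, combos, seed, n_random_inits):
    n_runs = n_random_inits + 1
    wH, wP, v, tau, f0, q0, index = _stack_runs(
        masters, combos, n_random_inits, seed)
    # matrix indices in _stack_runs are chunk-local; shift for seeds: the
    # seed derivation must be global, so re-derive inits with global indices
    eq = equal_state()
    r = 0
    for mi_local in range(len(masters)):
        for ci in range(len(combos)):
            for run in range(n_runs):
                if run < n_random_inits:
                    state = random_state(_run_seed(seed, offset + mi_local, ci, run))
                    f0[r], q0[r] = state.f, state.q
                r += 1
    p0 = combos[0]
    batch = simulate_batch(wH, wP, v, tau, f0, q0,
                           n_generations=p0.n_generations, burn_in=p0.burn_in)
    outcomes = outcomes_from_batch(batch)
    tuples = outcome_tuples(outcomes)
    rows = []
    for mi_local in range(len(masters)):
        for ci, p in enumerate(combos):
            base = (mi_local * len(combos) + ci) * n_runs
            model_tuples = tuples[base:base + n_runs]
            ambiguous = len(set(model_tuples)) > 1
            r_eq = base + n_runs - 1
            rec = records[offset + mi_local] if records else None
            rows.append({
                "matrix_id": rec.id if rec else f"m{offset + mi_local:05d}",
                "S_HP": rec.S_HP if rec else np.nan,
                "S_SP": rec.S_SP if rec else np.nan,
                "S_HS": rec.S_HS if rec else np.nan,
                "sampler": rec.sampler if rec else "unknown",
                "s_H": p.s_H, "s_P": p.s_P, "c": p.c, "v": p.v, "tau": p.tau,
                "trivial": p.c >= p.s_H,
                "ambiguous": ambiguous,
                "degenerate": bool(outcomes["degenerate"][r_eq]),
                "cycling": bool(outcomes["cycling"][r_eq]),
                "n_surviving_assoc": int(
                    outcomes["surviving_associations"][r_eq].sum()),
                "surviving_associations": "|".join(
                    ASSOCIATION_LABELS[a] for a in range(6)
                    if outcomes["surviving_associations"][r_eq, a]),
                "both_host_alleles": bool(
                    outcomes["surviving_host_alleles"][r_eq].all()),
                "both_symbiont_alleles": bool(
                    outcomes["surviving_symbiont_alleles"][r_eq].all()),
                "both_parasite_alleles": bool(
                    outcomes["surviving_parasite_alleles"][r_eq].all()),
                "mean_wH": float(outcomes["mean_wH"][r_eq]),
                "mean_wP": float(outcomes["mean_wP"][r_eq]),
            })
    return pd.DataFrame(rows)


def analysis_bin(score: float | np.ndarray) -> np.ndarray:
    """Analysis binning: bin 0 holds exactly the non-specific matrices
    (S = 0); bins 1..10 are (0, 0.1], (0.1, 0.2], ..., (0.9, 1.0].
    Missing scores map to bin -1 (unscored)."""
    s = np.asarray(score, dtype=float)
    with np.errstate(invalid="ignore"):
        b = np.ceil(np.nan_to_num(s) * 10).astype(int)
    bins = np.clip(np.where(s <= 0.0, 0, np.maximum(b, 1)), 0, 10)
    return np.where(np.isnan(s), -1, bins)


def summarize_by_bin(outcomes: pd.DataFrame, specificity_kind: str = "HP",
                     exclude_trivial: bool = True,
                     stratify: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Aggregate per-model outcomes into the 11 analysis bins.

    Reports, per bin (optionally stratified by parameter columns such as
    ``["v"]``): model count, fraction cycling, mean number of surviving
    associations, fractions of models retaining both alleles of each
    species, and mean host/parasite fitness.  Empty bins appear with count
    0 and null aggregates; excluded trivial models are counted.
    """
    col = f"S_{specificity_kind}"
    if col not in outcomes.columns:
        raise ValueError(f"outcome table lacks specificity column {col}")
    df = outcomes.copy()
    df["bin"] = analysis_bin(df[col].to_numpy())
    df = df[df["bin"] >= 0]  # drop models with no specificity score
    n_excluded = 0
    if exclude_trivial and "trivial" in df.columns:
        n_excluded = int(df["trivial"].sum())
        df = df[~df["trivial"]]
    keys = ["bin", *(stratify or [])]
    agg = df.groupby(keys, observed=True).agg(
        n_models=("cycling", "size"),
        frac_cycling=("cycling", "mean"),
        mean_n_surviving_assoc=("n_surviving_assoc", "mean"),
        frac_both_host_alleles=("both_host_alleles", "mean"),
        frac_both_symbiont_alleles=("both_symbiont_alleles", "mean"),
        frac_both_parasite_alleles=("both_parasite_alleles", "mean"),
        frac_ambiguous=("ambiguous", "mean"),
        mean_wH=("mean_wH", "mean"),
        mean_wP=("mean_wP", "mean"),
    ).reset_index()
    if not stratify:
        full = pd.DataFrame({"bin": np.arange(11)})
        agg = full.merge(agg, on="bin", how="left")
        agg["n_models"] = agg["n_models"].fillna(0).astype(int)
    agg.attrs["n_excluded_trivial"] = n_excluded
    agg.attrs["specificity_kind"] = specificity_kind
    return agg


def run_ambiguity_study(seed: int = 0, n_matrices: int = 50,
                        n_combos: int = 12, n_random_inits: int = 10,
                        n_generations: int = 20000, burn_in: int = 10000
                        ) -> dict:
    """Fraction of models whose 11 differently initialised runs disagree.

    Draws ``n_matrices`` protection-constrained i.u.d. master matrices,
    crosses them with a stratified subset of ``n_combos`` non-trivial grid
    combinations, simulates each model under ``n_random_inits`` random
    starts plus the equal-frequency start, and reports the fraction of
    non-trivial models classified ambiguous.
    """
    from .sampling import _draw_accepted

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    masters = [MasterMatrix(e) for e in _draw_accepted(rng, n_matrices, "iud")]
    combos = ParameterGrid().representative_nontrivial(
        n_combos, n_generations=n_generations, burn_in=burn_in)
    table = run_grid(masters, combos, seed=seed,
                     n_random_inits=n_random_inits)
    nontrivial = table[~table.trivial]
    return {
        "table": table,
        "n_models": int(len(nontrivial)),
        "n_ambiguous": int(nontrivial.ambiguous.sum()),
        "ambiguous_fraction": float(nontrivial.ambiguous.mean()),
    }


def run_canonical_study(deltas: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
                        costs: Sequence[float] = (0.0, 0.05, 0.1, 0.15, 0.2,
                                                  0.25, 0.3, 0.4),
                        s_H: float = 0.5, s_P: float = 0.5,
                        seed: int = 0, n_generations: int = 20000,
                        burn_in: int = 10000) -> dict:
    """Symbiont fate in the canonical MA and GFG models.

    Simulates both models for every (delta, c) cell under perfect maternal
    inheritance (v=1) and no horizontal transfer (tau=0), from a seeded
    random start (the equal-frequency start sits on the invariant symmetric
    manifold of these exactly symmetric matrices, where antagonist
    frequencies never move).  Reports per cell the symbiont fate (fixed /
    extinct / polymorphic), the cycling flag and the mean frequencies of
    the two symbiont alleles, plus the empirical fixation cost threshold
    c*(delta): the largest tested cost at which symbionts persist.
    """
    init = random_state(np.random.default_rng(np.random.SeedSequence([seed, 0])))
    cells = [(kind, d, c) for kind in ("MA", "GFG")
             for d in deltas for c in costs]
    R = len(cells)
    wH = np.empty((R, 6, 2))
    wP = np.empty((R, 2, 6))
    f0 = np.tile(init.f, (R, 1))
    q0 = np.tile(init.q, (R, 1))
    for r, (kind, d, c) in enumerate(cells):
        master = make_ma_master(d) if kind == "MA" else make_gfg_master(d)
        fit = derive_fitness_pair(master, s_H, s_P, c)
        wH[r] = fit.host_fitness
        wP[r] = fit.parasite_fitness
    batch = simulate_batch(wH, wP, np.ones(R), np.zeros(R), f0, q0,
                           n_generations=n_generations, burn_in=burn_in)
    out = outcomes_from_batch(batch)
    rows = []
    for r, (kind, d, c) in enumerate(cells):
        free = batch.mean_f[r, [0, 3]].sum()
        sym = batch.mean_f[r, [1, 2, 4, 5]].sum()
        fate = ("fixed" if free < LOSS_THRESHOLD
                else "extinct" if sym < LOSS_THRESHOLD else "polymorphic")
        rows.append({
            "model": kind, "delta": d, "c": c, "fate": fate,
            "cycling": bool(out["cycling"][r]),
            "mean_S1": float(batch.mean_f[r, [1, 4]].sum()),
            "mean_S2": float(batch.mean_f[r, [2, 5]].sum()),
            "mean_wH": float(batch.mean_wH[r]),
            "mean_wP": float(batch.mean_wP[r]),
        })
    table = pd.DataFrame(rows)
    thresholds = {}
    for kind in ("MA", "GFG"):
        for d in deltas:
            cell = table[(table.model == kind) & (table.delta == d)]
            kept = cell[cell.fate != "extinct"]
            thresholds[(kind, d)] = float(kept.c.max()) if len(kept) else np.nan
    return {"table": table, "fixation_thresholds": thresholds,
            "params": {"s_H": s_H, "s_P": s_P, "v": 1.0, "tau": 0.0,
                       "seed": seed}}


# --- result-table serialisation -----------------------------------------

def _table_checksum(csv_text: str) -> str:
    return hashlib.sha256(csv_text.encode()).hexdigest()[:16]


def write_results(table: pd.DataFrame, path: str | Path,
                  seed: Optional[int] = None, **metadata) -> None:
    """Write an outcome/summary table as CSV with a commented metadata
    header (package version, schema version, seed, thresholds, checksum)."""
    meta = {
        "package_version": _pkg_version,
        "schema_version": _SCHEMA_VERSION,
        "loss_threshold": LOSS_THRESHOLD,
        "seed": seed,
        **metadata,
    }
    body = table.to_csv(index=False)
    meta["checksum"] = _table_checksum(body)
    lines = [f"# {json.dumps({k: v})[1:-1]}" for k, v in meta.items()]
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results`, verifying schema and
    checksum; a missing seed only warns."""
    text = Path(path).read_text()
    meta = {}
    lines = text.splitlines(keepends=True)
    n_meta = 0
    for line in lines:
        if not line.startswith("# "):
            break
        key, _, raw = line[2:].partition(":")
        meta[json.loads(key)] = json.loads(raw)
        n_meta += 1
    body = "".join(lines[n_meta:])
    schema = meta.get("schema_version")
    if schema is not None and schema != _SCHEMA_VERSION:
        raise ValueError(
            f"result file schema version {schema} != supported {_SCHEMA_VERSION}")
    if "checksum" in meta and _table_checksum(body) != meta["checksum"]:
        raise ValueError(f"checksum mismatch in {path}: refusing partial or "
                         "corrupted results")
    if meta and meta.get("seed") is None:
        warnings.warn(f"result file {path} lacks seed metadata", UserWarning)
    from io import StringIO

    table = pd.read_csv(StringIO(body))
    table.attrs["metadata"] = meta
    return table
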