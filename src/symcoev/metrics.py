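"""Trajectory classification: cycling, loss, diversity, ambiguity.

All survival calls use one threshold: a class (association, or the summed
classes carrying an allele) counts as lost when its mean frequency over the
assessment window falls below 1e-3.  A model *cycles* when at least one
association frequency shows six or more local extrema in the window with
inter-extremum amplitudes that do not decrease.  A model is *ambiguous*
when eleven differently initialised runs (ten uniform-random starting
frequency vectors plus one equal-frequency run) disagree in their discrete
outcome (surviving associations, surviving parasite alleles, cycling
flag); the reported summary always comes from the equal-frequency run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrices import MasterMatrix, ASSOCIATION_LABELS, derive_fitness_pair
from .dynamics import (BatchSummary, SimParams, Trajectory, classify_trivial,
                       equal_state, random_state, simulate_batch)

__all__ = [
    "LOSS_THRESHOLD",
    "OutcomeSummary",
    "count_local_extrema",
    "detect_cycling",
    "association_lost",
    "allele_survival",
    "classify_model",
    "outcomes_from_batch",
    "summarize_trajectory",
]

#: Mean-frequency threshold below which a class is declared lost.
LOSS_THRESHOLD = 1e-3
#: Minimal number of local extrema for a series to count as cycling.
MIN_EXTREMA = 6
#: Relative tolerance of the amplitude non-decrease test.
AMPLITUDE_RTOL = 1e-3
#: First-difference changes at or below this size are ignored.
EXTREMA_TOL = 1e-6

# association -> carried alleles, canonical ordering
_HOST_OF = np.array([0, 0, 0, 1, 1, 1])
_SYM_OF = np.array([-1, 0, 1, -1, 0, 1])   # -1 = symbiont-free


@dataclass(frozen=True)
class OutcomeSummary:
    """Discrete classification of one model (one master matrix + one
    parameter combination), evaluated on the equal-frequency run."""

    surviving_associations: tuple[str, ...]
    surviving_host_alleles: tuple[str, ...]
    surviving_symbiont_alleles: tuple[str, ...]
    surviving_parasite_alleles: tuple[str, ...]
    cycling: bool
    mean_wH: float
    mean_wP: float
    trivial: bool
    ambiguous: bool
    degenerate: bool


def count_local_extrema(series: Sequence[float], tol: float = EXTREMA_TOL
                        ) -> tuple[int, list[int], list[float]]:
    """Count strict local extrema of a series, ignoring tiny wiggles.

    First differences of magnitude <= ``tol`` are dropped; an extremum is
    recorded wherever the sign of the remaining differences flips, at the
    index preceding the new significant move.  Endpoints are never extrema.
    Returns (count, positions, values).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to find interior extrema")
    positions: list[int] = []
    values: list[float] = []
    last_sign = 0
    for t in range(1, x.size):
        d = x[t] - x[t - 1]
        if abs(d) <= tol:
            continue
        s = 1 if d > 0 else -1
        if last_sign != 0 and s != last_sign:
            positions.append(t - 1)
            values.append(x[t - 1])
        last_sign = s
    return len(positions), positions, values


def _amplitude_nondecreasing(values: Sequence[float],
                             rtol: float = AMPLITUDE_RTOL) -> bool:
    """Mean of the last three inter-extremum amplitudes must reach
    (1 - rtol) times the mean of the first three."""
    amps = np.abs(np.diff(np.asarray(values, dtype=float)))
    if amps.size < 3:
        return False
    return amps[-3:].mean() >= (1.0 - rtol) * amps[:3].mean()


def detect_cycling(traj: Trajectory, tol: float = EXTREMA_TOL,
                   rtol: float = AMPLITUDE_RTOL) -> bool:
    """True iff some association series in the assessment window has at
    least six local extrema whose amplitudes do not decrease."""
    for a in range(6):
        n, _, values = count_local_extrema(traj.association_series(a), tol=tol)
        if n >= MIN_EXTREMA and _amplitude_nondecreasing(values, rtol=rtol):
            return True
    return False


def association_lost(traj: Trajectory, association: int,
                     threshold: float = LOSS_THRESHOLD) -> bool:
    """Lost iff the association's mean frequency over the window < 1e-3."""
    return float(traj.f[traj.assessment, association].mean()) < threshold


def allele_survival(traj: Trajectory, threshold: float = LOSS_THRESHOLD
                    ) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Surviving host, symbiont and parasite alleles of a trajectory.

    An allele survives iff the summed frequency of the classes carrying it
    has assessment-window mean >= the loss threshold.
    """
    window_f = traj.f[traj.assessment]
    window_q = traj.q[traj.assessment]
    hosts = tuple(f"H{i+1}" for i in range(2)
                  if window_f[:, _HOST_OF == i].sum(axis=1).mean() >= threshold)
    syms = tuple(f"S{s+1}" for s in range(2)
                 if window_f[:, _SYM_OF == s].sum(axis=1).mean() >= threshold)
    pars = tuple(f"P{p+1}" for p in range(2)
                 if window_q[:, p].mean() >= threshold)
    return hosts, syms, pars


def summarize_trajectory(traj: Trajectory,
                         threshold: float = LOSS_THRESHOLD) -> dict:
    """Window means, survival sets and cycling flag of a single trajectory."""
    surviving = tuple(ASSOCIATION_LABELS[a] for a in range(6)
                      if not association_lost(traj, a, threshold))
    hosts, syms, pars = allele_survival(traj, threshold)
    return {
        "surviving_associations": surviving,
        "surviving_host_alleles": hosts,
        "surviving_symbiont_alleles": syms,
        "surviving_parasite_alleles": pars,
        "cycling": detect_cycling(traj),
        "mean_wH": float(traj.mean_wH[traj.assessment].mean()),
        "mean_wP": float(traj.mean_wP[traj.assessment].mean()),
        "degenerate": traj.degenerate,
    }


def outcomes_from_batch(batch: BatchSummary,
                        threshold: float = LOSS_THRESHOLD,
                        rtol: float = AMPLITUDE_RTOL) -> dict[str, np.ndarray]:
    """Vectorised discrete outcomes for every run of a batch summary."""
    surv_assoc = batch.mean_f >= threshold                      # (R, 6)
    surv_host = np.stack([batch.mean_f[:, _HOST_OF == i].sum(axis=1) >= threshold
                          for i in range(2)], axis=1)
    surv_sym = np.stack([batch.mean_f[:, _SYM_OF == s].sum(axis=1) >= threshold
                         for s in range(2)], axis=1)
    surv_par = batch.mean_q >= threshold                        # (R, 2)
    enough = batch.n_extrema >= MIN_EXTREMA
    with np.errstate(invalid="ignore", divide="ignore"):
        first_mean = batch.first_amps.mean(axis=2)
        last_mean = batch.last_amps.mean(axis=2)
        nondecr = (batch.n_amps >= 3) & \
            (last_mean >= (1.0 - rtol) * first_mean)
    cycling = (enough & nondecr).any(axis=1)                    # (R,)
    return {
        "surviving_associations": surv_assoc,
        "surviving_host_alleles": surv_host,
        "surviving_symbiont_alleles": surv_sym,
        "surviving_parasite_alleles": surv_par,
        "cycling": cycling,
        "mean_wH": batch.mean_wH,
        "mean_wP": batch.mean_wP,
        "degenerate": batch.degenerate,
    }


def outcome_tuples(outcomes: dict[str, np.ndarray]) -> list[tuple]:
    """Discrete outcome tuple per run, the unit of the ambiguity test."""
    R = outcomes["cycling"].shape[0]
    return [
        (
            tuple(map(bool, outcomes["surviving_associations"][r])),
            tuple(map(bool, outcomes["surviving_parasite_alleles"][r])),
            bool(outcomes["cycling"][r]),
            bool(outcomes["degenerate"][r]),
        )
        for r in range(R)
    ]


def classify_model(master: MasterMatrix, params: SimParams, seed: int,
                   n_random_inits: int = 10,
                   threshold: float = LOSS_THRESHOLD) -> OutcomeSummary:
    """Simulate a model under 10 random and 1 equal initialisation and
    classify it.

    The ten random starting frequency vectors are Dirichlet(1) draws on
    both simplices, seeded deterministically from ``seed``.  The summary
    comes from the equal-frequency run; the model is ambiguous when the
    eleven discrete outcome tuples are not all identical.
    """
    R = n_random_inits + 1
    fitness = derive_fitness_pair(master, params.s_H, params.s_P, params.c)
    wH = np.broadcast_to(fitness.host_fitness, (R, 6, 2))
    wP = np.broadcast_to(fitness.parasite_fitness, (R, 2, 6))
    f0 = np.empty((R, 6))
    q0 = np.empty((R, 2))
    for r in range(n_random_inits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        state = random_state(rng)
        f0[r], q0[r] = state.f, state.q
    eq = equal_state()
    f0[-1], q0[-1] = eq.f, eq.q
    batch = simulate_batch(wH, wP, np.full(R, params.v), np.full(R, params.tau),
                           f0, q0, n_generations=params.n_generations,
                           burn_in=params.burn_in)
    outcomes = outcomes_from_batch(batch, threshold=threshold)
    tuples = outcome_tuples(outcomes)
    ambiguous = len(set(tuples)) > 1
    r = R - 1  # equal-frequency run
    return OutcomeSummary(
        surviving_associations=tuple(
            ASSOCIATION_LABELS[a] for a in range(6)
            if outcomes["surviving_associations"][r, a]),
        surviving_host_alleles=tuple(
            f"H{i+1}" for i in range(2)
            if outcomes["surviving_host_alleles"][r, i]),
        surviving_symbiont_alleles=tuple(
            f"S{s+1}" for s in range(2)
            if outcomes["surviving_symbiont_alleles"][r, s]),
        surviving_parasite_alleles=tuple(
            f"P{p+1}" for p in range(2)
            if outcomes["surviving_parasite_alleles"][r, p]),
        cycling=bool(outcomes["cycling"][r]),
        mean_wH=float(outcomes["mean_wH"][r]),
        mean_wP=float(outcomes["mean_wP"][r]),
        trivial=classify_trivial(params),
        ambiguous=ambiguous,
        degenerate=bool(outcomes["degenerate"][r]),
    )
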