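"""Deterministic discrete-generation coevolution dynamics.

Each generation applies, in order: horizontal symbiont transmission
(mass-action colonisation of symbiont-free hosts), simultaneous
frequency-dependent selection on hosts and parasites (discrete replicator
update weighted by antagonist frequencies), and vertical symbiont loss (a
constant fraction 1-v of symbiont-bearing hosts loses the symbiont).  The
recorded state is post-loss.  Populations are infinite: only frequencies
are tracked, and every sub-step conserves the two simplices.

Two execution paths are provided.  :func:`simulate` integrates a single
model and records the full trajectory.  :func:`simulate_batch` advances
many independent models in lock-step with vectorised numpy operations and
accumulates assessment-window statistics (frequency means, mean fitnesses,
local extrema of every association series and their amplitudes) online, so
ensemble sweeps never materialise trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .matrices import MasterMatrix, derive_fitness_pair, FitnessPair

__all__ = [
    "PopulationState",
    "SimParams",
    "Trajectory",
    "BatchSummary",
    "DegenerateModelError",
    "horizontal_step",
    "selection_step",
    "loss_step",
    "simulate",
    "simulate_batch",
    "classify_trivial",
    "equal_state",
    "random_state",
]

_FREQ_ATOL = 1e-12
#: Frequencies below this are treated as extinct.  The floor sits just
#: above the subnormal range: genotype-frequency oscillations routinely
#: visit astronomically small but dynamically recoverable values, and a
#: higher floor would convert sustained cycles into spurious fixations.
_FLOOR = 1e-300
_S1 = np.array([1, 4])
_S2 = np.array([2, 5])
_FREE = np.array([0, 3])


class DegenerateModelError(RuntimeError):
    """Mean fitness hit zero: total extinction under selection."""


@dataclass(frozen=True)
class PopulationState:
    """Association frequencies f (6) and parasite genotype frequencies q (2)."""

    f: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if f.shape != (6,) or q.shape != (2,):
            raise ValueError("state must hold 6 association and 2 parasite frequencies")
        if np.any(f < 0) or np.any(q < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "q", q)


def equal_state() -> PopulationState:
    """Equal starting frequencies of all genotypes."""
    return PopulationState(np.full(6, 1 / 6), np.full(2, 1 / 2))


def random_state(rng: np.random.Generator) -> PopulationState:
    """Uniform (Dirichlet(1)) random frequency vectors on both simplices."""
    return PopulationState(rng.dirichlet(np.ones(6)), rng.dirichlet(np.ones(2)))


@dataclass(frozen=True)
class SimParams:
    """Model parameters.

    s_H, s_P : maximal selection strength on hosts / parasites, in [0, 1].
    c        : fitness cost of harbouring symbionts, in [0, 1].
    v        : fidelity of vertical symbiont transmission, in [0, 1];
               a fraction 1-v of symbiont-bearing hosts loses the symbiont
               each generation.
    tau      : mass-action basal rate of horizontal symbiont transmission.
    """

    s_H: float
    s_P: float
    c: float
    v: float = 1.0
    tau: float = 0.0
    n_generations: int = 20000
    burn_in: int = 10000

    def __post_init__(self) -> None:
        for name in ("s_H", "s_P", "c", "v"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"parameter {name}={val} outside [0, 1]")
        if self.tau < 0:
            raise ValueError(f"parameter tau={self.tau} must be non-negative")
        if not 0 <= self.burn_in < self.n_generations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_generations")


def classify_trivial(params: SimParams) -> bool:
    """True iff the symbiont cost reaches the maximal parasite-inflicted
    damage (c >= s_H), in which case symbionts can never confer a net
    benefit and, absent frequent horizontal transfer, inevitably go
    extinct."""
    return params.c >= params.s_H


@dataclass(frozen=True)
class Trajectory:
    """Per-generation record of a single simulation (post-loss states)."""

    f: np.ndarray            # (n_generations, 6)
    q: np.ndarray            # (n_generations, 2)
    mean_wH: np.ndarray      # (n_generations,)
    mean_wP: np.ndarray
    params: SimParams
    degenerate: bool = False
    degenerate_generation: Optional[int] = None

    @property
    def assessment(self) -> slice:
        return slice(self.params.burn_in, self.params.n_generations)

    def association_series(self, a: int) -> np.ndarray:
        return self.f[self.assessment, a]


def horizontal_step(state: PopulationState, tau: float) -> PopulationState:
    """Symbionts colonise symbiont-free hosts at mass-action rate tau.

    The flux from (i, none) to (i, s) is ``tau * f[(i,none)] * F_s`` where
    F_s is the total frequency of carriers of symbiont allele s, regardless
    of host background; acquisition preserves the host allele, and
    already-infected hosts are never superinfected.
    """
    f = state.f.copy()
    total_rate = tau * (f[_S1].sum() + f[_S2].sum())
    if total_rate > 1.0:
        warnings.warn("horizontal transmission flux capped to the available "
                      "symbiont-free hosts", RuntimeWarning)
        tau = tau / total_rate
    for host in range(2):
        free = 3 * host
        outflow = tau * f[free]
        f[free + 1] += outflow * state.f[_S1].sum()
        f[free + 2] += outflow * state.f[_S2].sum()
        f[free] -= outflow * (state.f[_S1].sum() + state.f[_S2].sum())
    return PopulationState(f, state.q)


def selection_step(state: PopulationState, fitness: FitnessPair
                   ) -> tuple[PopulationState, float, float]:
    """Simultaneous replicator update of hosts and parasites.

    Each genotype's fitness is the frequency-weighted average of its row of
    the fitness matrix over the antagonist's *pre-selection* frequencies;
    dividing by the mean fitness renormalises each simplex.
    """
    fit_h = fitness.host_fitness @ state.q          # (6,)
    fit_p = fitness.parasite_fitness @ state.f      # (2,)
    mean_wH = float(state.f @ fit_h)
    mean_wP = float(state.q @ fit_p)
    if mean_wH <= 0.0 or mean_wP <= 0.0:
        raise DegenerateModelError(
            f"mean fitness vanished (host {mean_wH}, parasite {mean_wP})")
    return (PopulationState(state.f * fit_h / mean_wH,
                            state.q * fit_p / mean_wP),
            mean_wH, mean_wP)


def loss_step(state: PopulationState, v: float) -> PopulationState:
    """A fraction 1-v of symbiont-bearing hosts loses the symbiont."""
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"parameter v={v} outside [0, 1]")
    f = state.f.copy()
    for host in range(2):
        free = 3 * host
        lost = (1.0 - v) * (f[free + 1] + f[free + 2])
        f[free + 1] *= v
        f[free + 2] *= v
        f[free] += lost
    return PopulationState(f, state.q)


def _clamp(vec: np.ndarray) -> np.ndarray:
    vec = np.where(vec < _FLOOR, 0.0, vec)
    return vec / vec.sum()


def simulate(master: MasterMatrix, params: SimParams,
             init: Optional[PopulationState] = None) -> Trajectory:
    """Integrate one model for ``params.n_generations`` generations.

    Applies horizontal transmission, selection and symbiont loss in that
    order each generation and records the post-loss state together with the
    generation's mean host and parasite fitness.  Fully deterministic.  If
    selection drives a mean fitness to zero the trajectory is truncated
    (remaining records repeat the last state) and flagged degenerate.
    """
    if init is None:
        init = equal_state()
    fitness = derive_fitness_pair(master, params.s_H, params.s_P, params.c)
    n = params.n_generations
    f_rec = np.empty((n, 6))
    q_rec = np.empty((n, 2))
    wh_rec = np.empty(n)
    wp_rec = np.empty(n)
    state = init
    degenerate = False
    degen_gen: Optional[int] = None
    for t in range(n):
        if not degenerate:
            try:
                state = horizontal_step(state, params.tau)
                state, mean_wH, mean_wP = selection_step(state, fitness)
                state = loss_step(state, params.v)
                state = PopulationState(_clamp(state.f), _clamp(state.q))
            except DegenerateModelError:
                degenerate = True
                degen_gen = t
                mean_wH = mean_wP = 0.0
        f_rec[t] = state.f
        q_rec[t] = state.q
        wh_rec[t] = mean_wH
        wp_rec[t] = mean_wP
    return Trajectory(f=f_rec, q=q_rec, mean_wH=wh_rec, mean_wP=wp_rec,
                      params=params, degenerate=degenerate,
                      degenerate_generation=degen_gen)


@dataclass
class BatchSummary:
    """Assessment-window accumulators for a batch of R lock-step runs."""

    mean_f: np.ndarray        # (R, 6) window mean of association frequencies
    mean_q: np.ndarray        # (R, 2)
    mean_wH: np.ndarray       # (R,) window mean of mean host fitness
    mean_wP: np.ndarray       # (R,)
    n_extrema: np.ndarray     # (R, 6) local extrema per association series
    first_amps: np.ndarray    # (R, 6, 3) first three inter-extremum amplitudes
    last_amps: np.ndarray     # (R, 6, 3) ring buffer of the last three
    n_amps: np.ndarray        # (R, 6)
    degenerate: np.ndarray    # (R,) bool
    final_f: np.ndarray       # (R, 6)
    final_q: np.ndarray       # (R, 2)


def simulate_batch(wH: np.ndarray, wP: np.ndarray, v: np.ndarray,
                   tau: np.ndarray, f0: np.ndarray, q0: np.ndarray,
                   n_generations: int = 20000, burn_in: int = 10000,
                   extrema_tol: float = 1e-6) -> BatchSummary:
    """Advance R independent models in lock-step and accumulate metrics.

    Parameters are stacked along the first axis: ``wH`` (R,6,2), ``wP``
    (R,2,6), ``v``/``tau`` (R,), ``f0`` (R,6), ``q0`` (R,2).  The update
    rule per generation is identical to :func:`simulate`; equivalence of
    the two paths is asserted in the test suite.  Runs whose mean fitness
    vanishes are frozen and flagged degenerate.
    """
    f = np.array(f0, dtype=float)
    q = np.array(q0, dtype=float)
    R = f.shape[0]
    v = np.broadcast_to(np.asarray(v, dtype=float), (R,)).copy()
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (R,)).copy()
    alive = np.ones(R, dtype=bool)

    window = n_generations - burn_in
    sum_f = np.zeros((R, 6))
    sum_q = np.zeros((R, 2))
    sum_wh = np.zeros(R)
    sum_wp = np.zeros(R)
    # online extrema tracking (assessment window only)
    prev = np.zeros((R, 6))
    last_sign = np.zeros((R, 6), dtype=np.int8)
    n_extrema = np.zeros((R, 6), dtype=np.int64)
    last_ext = np.zeros((R, 6))
    has_ext = np.zeros((R, 6), dtype=bool)
    first_amps = np.zeros((R, 6, 3))
    last_amps = np.zeros((R, 6, 3))
    n_amps = np.zeros((R, 6), dtype=np.int64)

    loss = (1.0 - v)[:, None]
    for t in range(n_generations):
        # horizontal transmission
        F1 = f[:, _S1].sum(axis=1)
        F2 = f[:, _S2].sum(axis=1)
        rate = tau * (F1 + F2)
        eff_tau = np.where(rate > 1.0, tau / np.maximum(rate, 1e-300), tau)
        out1 = eff_tau * F1
        out2 = eff_tau * F2
        fh = f.copy()
        for host in range(2):
            free = 3 * host
            fh[:, free + 1] += f[:, free] * out1
            fh[:, free + 2] += f[:, free] * out2
            fh[:, free] -= f[:, free] * (out1 + out2)
        # selection (simultaneous, pre-selection antagonist frequencies)
        fit_h = np.einsum("rap,rp->ra", wH, q)
        fit_p = np.einsum("rpa,ra->rp", wP, fh)
        mean_wh = np.einsum("ra,ra->r", fh, fit_h)
        mean_wp = np.einsum("rp,rp->r", q, fit_p)
        dying = alive & ((mean_wh <= 0.0) | (mean_wp <= 0.0))
        alive = alive & ~dying
        upd = alive
        safe_wh = np.where(mean_wh > 0, mean_wh, 1.0)
        safe_wp = np.where(mean_wp > 0, mean_wp, 1.0)
        f_new = fh * fit_h / safe_wh[:, None]
        q_new = q * fit_p / safe_wp[:, None]
        # symbiont loss
        for host in range(2):
            free = 3 * host
            lost = loss[:, 0] * (f_new[:, free + 1] + f_new[:, free + 2])
            f_new[:, free + 1] *= v
            f_new[:, free + 2] *= v
            f_new[:, free] += lost
        # numerical floor + renormalisation
        f_new = np.where(f_new < _FLOOR, 0.0, f_new)
        q_new = np.where(q_new < _FLOOR, 0.0, q_new)
        f_new /= f_new.sum(axis=1, keepdims=True)
        q_new /= q_new.sum(axis=1, keepdims=True)
        f = np.where(upd[:, None], f_new, f)
        q = np.where(upd[:, None], q_new, q)

        if t >= burn_in:
            sum_f += f
            sum_q += q
            sum_wh += np.where(upd, mean_wh, 0.0)
            sum_wp += np.where(upd, mean_wp, 0.0)
            if t == burn_in:
                prev[:] = f
            else:
                d = f - prev
                sig = np.abs(d) > extrema_tol
                s = np.where(d > 0, 1, -1).astype(np.int8)
                flip = sig & (last_sign != 0) & (s != last_sign)
                if flip.any():
                    amp_mask = flip & has_ext
                    if amp_mask.any():
                        amps = np.abs(prev - last_ext)
                        pos_first = np.clip(n_amps, 0, 2)
                        pos_last = n_amps % 3
                        ridx, aidx = np.nonzero(amp_mask)
                        fresh = n_amps[ridx, aidx] < 3
                        first_amps[ridx[fresh], aidx[fresh],
                                   pos_first[ridx[fresh], aidx[fresh]]] = \
                            amps[ridx[fresh], aidx[fresh]]
                        last_amps[ridx, aidx, pos_last[ridx, aidx]] = amps[ridx, aidx]
                        n_amps[amp_mask] += 1
                    last_ext = np.where(flip, prev, last_ext)
                    has_ext |= flip
                    n_extrema[flip] += 1
                last_sign = np.where(sig, s, last_sign)
                prev[:] = f
    return BatchSummary(
        mean_f=sum_f / window, mean_q=sum_q / window,
        mean_wH=sum_wh / window, mean_wP=sum_wp / window,
        n_extrema=n_extrema, first_amps=first_amps, last_amps=last_amps,
        n_amps=n_amps, degenerate=~alive, final_f=f, final_q=q,
    )
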