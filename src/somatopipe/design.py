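"""Block schedules, HRF bases, and first-level design matrices.

The experimental design is a three-condition motor block paradigm
(left-hand, right-hand, face movement): 12-s movement blocks each followed
by a 6-s rest, eight blocks per condition per run, in a counterbalanced
pseudo-random order, acquired at TR = 2.5 s with 179 volumes per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("left_hand", "right_hand", "face")
REST = "rest"

DEFAULT_TR_S = 2.5
DEFAULT_N_VOLUMES = 179
BLOCK_DURATION_S = 12.0
REST_DURATION_S = 6.0
BLOCKS_PER_CONDITION = 8


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class BlockSchedule:
    """Ordered condition blocks (movement and interleaved rest) for one run."""

    run_index: int
    blocks: list[Block]
    tr_s: float = DEFAULT_TR_S
    n_volumes: int = DEFAULT_N_VOLUMES
    lead_in_rest_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def movement_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition != REST]

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {c: 0 for c in CONDITIONS}
        for b in self.movement_blocks:
            counts[b.condition] = counts.get(b.condition, 0) + 1
        return counts

    def condition_order(self) -> list[str]:
        return [b.condition for b in self.movement_blocks]

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in self.blocks],
                "duration": [b.duration_s for b in self.blocks],
                "trial_type": [b.condition for b in self.blocks],
            }
        )

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        run_index: int = 0,
        tr_s: float = DEFAULT_TR_S,
        n_volumes: int = DEFAULT_N_VOLUMES,
    ) -> "BlockSchedule":
        blocks = [
            Block(str(r.trial_type), float(r.onset), float(r.duration))
            for r in events.itertuples()
        ]
        blocks.sort(key=lambda b: b.onset_s)
        lead_in = blocks[0].onset_s if blocks else 0.0
        return cls(run_index, blocks, tr_s=tr_s, n_volumes=n_volumes,
                   lead_in_rest_s=lead_in)


def _has_triple_repeat(order: list[str]) -> bool:
    return any(order[i] == order[i + 1] == order[i + 2]
               for i in range(len(order) - 2))


def _covers_quarters(order: list[str], conditions: tuple[str, ...]) -> bool:
    n = len(order)
    q = n // 4
    for k in range(4):
        chunk = order[k * q:(k + 1) * q] if k < 3 else order[3 * q:]
        if any(c not in chunk for c in conditions):
            return False
    return True


def _sample_order(rng: np.random.Generator, blocks_per_condition: int) -> list[str]:
    pool = list(CONDITIONS) * blocks_per_condition
    for _ in range(10_000):
        order = [pool[i] for i in rng.permutation(len(pool))]
        if _has_triple_repeat(order):
            continue
        if blocks_per_condition >= 4 and not _covers_quarters(order, CONDITIONS):
            continue
        return order
    raise RuntimeError("failed to sample a counterbalanced block order")


def make_block_schedule(
    run_index: int,
    order_seed: int,
    tr_s: float = DEFAULT_TR_S,
    n_volumes: int = DEFAULT_N_VOLUMES,
    blocks_per_condition: int = BLOCKS_PER_CONDITION,
    block_duration_s: float = BLOCK_DURATION_S,
    rest_duration_s: float = REST_DURATION_S,
) -> BlockSchedule:
    """Pseudo-randomised counterbalanced block schedule for one run.

    Each movement block is followed by a rest block; no condition occurs
    three or more times consecutively, and with the default eight blocks
    per condition every condition appears in every ordinal quarter of the
    run. A leading rest period pads the task structure to the nominal run
    length ``n_volumes * tr_s``.
    """
    rng = np.random.default_rng([int(order_seed), int(run_index)])
    order = _sample_order(rng, blocks_per_condition)

    task_s = len(order) * (block_duration_s + rest_duration_s)
    total_s = n_volumes * tr_s
    lead_in = total_s - task_s
    if lead_in < 0:
        raise ValueError(
            f"schedule of {task_s} s does not fit in {n_volumes} volumes "
            f"at TR {tr_s} s"
        )
    blocks: list[Block] = []
    t = lead_in
    for cond in order:
        blocks.append(Block(cond, t, block_duration_s))
        t += block_duration_s
        blocks.append(Block(REST, t, rest_duration_s))
        t += rest_duration_s
    return BlockSchedule(run_index, blocks, tr_s=tr_s, n_volumes=n_volumes,
                         lead_in_rest_s=lead_in)


def make_run_schedules(
    n_runs: int,
    order_seed: int,
    **kwargs,
) -> list[BlockSchedule]:
    """Schedules for all runs of a session, each with a distinct block order."""
    schedules: list[BlockSchedule] = []
    seen: set[tuple[str, ...]] = set()
    for run in range(n_runs):
        bump = 0
        while True:
            sched = make_block_schedule(run, order_seed + 100_003 * bump, **kwargs)
            key = tuple(sched.condition_order())
            if key not in seen:
                break
            bump += 1  # astronomically rare collision; resample
        seen.add(key)
        schedules.append(sched)
    return schedules


def schedule_duration(schedule: BlockSchedule) -> float:
    """Task-structure duration in seconds: movement blocks plus interleaved
    rests, excluding the lead-in rest (432 s for the default run)."""
    return float(sum(b.duration_s for b in schedule.blocks))


def nominal_volume_counts(
    schedules: list[BlockSchedule],
    tr_s: float | None = None,
    n_volumes: int | None = None,
) -> dict[str, int]:
    """Per-condition nominal volume counts across runs.

    Bookkeeping convention: each movement block contributes
    ``ceil(block_duration / tr)`` volumes; rest receives the remainder of
    the acquisition. With 4 runs of 179 volumes at TR 2.5 s this yields
    160 volumes per movement condition and 236 rest volumes.
    """
    if not schedules:
        return {c: 0 for c in (*CONDITIONS, REST)}
    tr = float(tr_s if tr_s is not None else schedules[0].tr_s)
    nv = int(n_volumes if n_volumes is not None else schedules[0].n_volumes)
    if any(s.tr_s != tr or s.n_volumes != nv for s in schedules):
        raise ValueError("all runs must share tr_s and n_volumes")
    counts: dict[str, int] = {c: 0 for c in CONDITIONS}
    total_movement = 0
    for sched in schedules:
        for b in sched.movement_blocks:
            nvol = math.ceil(b.duration_s / tr)
            counts[b.condition] = counts.get(b.condition, 0) + nvol
            total_movement += nvol
    counts[REST] = len(schedules) * nv - total_movement
    return counts


# --- HRF basis ---------------------------------------------------------------

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_RATIO = 6.0
HRF_DURATION_S = 32.0


@dataclass
class HRFBasis:
    """Canonical double-gamma HRF with temporal and dispersion derivatives.

    Bases are sampled on an oversampled grid (``dt = tr_s / oversampling``)
    and normalised to unit peak absolute value.
    """

    tr_s: float
    oversampling: int
    time_grid: np.ndarray
    bases: np.ndarray  # (3, len(time_grid))
    names: tuple[str, str, str] = ("canonical", "temporal_derivative",
                                   "dispersion_derivative")

    @property
    def dt(self) -> float:
        return self.tr_s / self.oversampling

    @property
    def canonical(self) -> np.ndarray:
        return self.bases[0]


def _double_gamma(t: np.ndarray, dispersion: float = 1.0) -> np.ndarray:
    peak = stats.gamma.pdf(t, HRF_PEAK_DELAY_S / dispersion, scale=dispersion)
    undershoot = stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY_S)
    return peak - undershoot / HRF_RATIO


def hrf_basis(tr_s: float = DEFAULT_TR_S, oversampling: int = 16) -> HRFBasis:
    """Three-function HRF basis: canonical + temporal + dispersion derivatives."""
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    dt = tr_s / oversampling
    t = np.arange(0.0, HRF_DURATION_S + dt / 2, dt)
    canonical = _double_gamma(t)
    temporal = np.gradient(canonical, dt)
    eps = 0.01
    dispersion = (canonical - _double_gamma(t, dispersion=1.0 + eps)) / eps
    bases = np.vstack([canonical, temporal, dispersion])
    bases /= np.abs(bases).max(axis=1, keepdims=True)
    return HRFBasis(tr_s=tr_s, oversampling=oversampling, time_grid=t,
                    bases=bases)


# --- Design matrix -----------------------------------------------------------


@dataclass
class DesignMatrix:
    """First-level design: task (condition x basis), nuisance, drift columns."""

    matrix: np.ndarray  # (n_volumes, P)
    labels: list[str]
    tr_s: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_indices(self, predicate) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if predicate(lab)]

    @property
    def task_indices(self) -> list[int]:
        return self.column_indices(lambda lab: lab.startswith("task:"))

    @property
    def canonical_indices(self) -> dict[str, int]:
        out = {}
        for i, lab in enumerate(self.labels):
            if lab.startswith("task:") and lab.endswith(":canonical"):
                out[lab.split(":")[1]] = i
        return out

    @property
    def derivative_indices(self) -> list[int]:
        return self.column_indices(
            lambda lab: lab.startswith("task:") and "derivative" in lab)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)


def _dct_drift(n_volumes: int, tr_s: float, highpass_s: float) -> np.ndarray:
    """Discrete-cosine drift set with periods longer than the cutoff.

    Column k is cos(pi * k * (2n + 1) / (2N)); its period is 2*N*tr/k, so
    k runs to floor(2 * N * tr / highpass).
    """
    total_s = n_volumes * tr_s
    n_cos = int(np.floor(2.0 * total_s / highpass_s))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_volumes))
            for k in range(1, n_cos + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def condition_regressors(
    schedule: BlockSchedule,
    basis: HRFBasis,
    conditions: tuple[str, ...] = CONDITIONS,
) -> dict[str, np.ndarray]:
    """Boxcar-convolved regressors sampled at volume acquisition times.

    Returns ``{condition: (n_basis, n_volumes) array}``; row order follows
    ``basis.names``.
    """
    dt = basis.dt
    n_fine = int(round(schedule.duration_s / dt))
    vol_idx = np.round(np.arange(schedule.n_volumes) * schedule.tr_s / dt)
    vol_idx = vol_idx.astype(int)
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        boxcar = np.zeros(n_fine)
        for b in schedule.blocks:
            if b.condition != cond:
                continue
            i0 = int(round(b.onset_s / dt))
            i1 = int(round((b.onset_s + b.duration_s) / dt))
            boxcar[i0:min(i1, n_fine)] = 1.0
        rows = [np.convolve(boxcar, base)[:n_fine][vol_idx] * dt
                for base in basis.bases]
        out[cond] = np.asarray(rows)
    return out


def build_design_matrix(
    schedule: BlockSchedule,
    basis: HRFBasis | None = None,
    nuisance=None,
    highpass_s: float | None = 90.0,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    Columns: per condition the boxcar convolved with each of the three HRF
    bases, then any nuisance regressors, then DCT drift regressors with
    periods above ``highpass_s`` and an intercept.

    ``nuisance`` may be a NuisanceMatrix (from :mod:`somatopipe.physio`),
    a 2-D array, or None; its row count must equal ``schedule.n_volumes``.
    """
    if basis is None:
        basis = hrf_basis(schedule.tr_s)
    regs = condition_regressors(schedule, basis)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for cond in CONDITIONS:
        for bi, bname in enumerate(basis.names):
            cols.append(regs[cond][bi])
            labels.append(f"task:{cond}:{bname}")

    if nuisance is not None:
        nmat = np.asarray(getattr(nuisance, "matrix", nuisance), dtype=float)
        if nmat.ndim != 2 or nmat.shape[0] != schedule.n_volumes:
            raise ValueError(
                f"nuisance has {nmat.shape[0] if nmat.ndim == 2 else '?'} rows, "
                f"expected {schedule.n_volumes}"
            )
        nlabels = getattr(nuisance, "labels",
                          [f"nuisance:{j}" for j in range(nmat.shape[1])])
        for j in range(nmat.shape[1]):
            cols.append(nmat[:, j])
            lab = nlabels[j]
            labels.append(lab if lab.startswith("nuisance:") else f"nuisance:{lab}")

    if highpass_s is not None:
        drift = _dct_drift(schedule.n_volumes, schedule.tr_s, highpass_s)
        for j in range(drift.shape[1]):
            cols.append(drift[:, j])
            labels.append(f"drift:cos{j + 1}")
    cols.append(np.ones(schedule.n_volumes))
    labels.append("drift:intercept")

    matrix = np.column_stack(cols)
    for i, lab in enumerate(labels):
        if lab.startswith("task:") and not np.any(matrix[:, i]):
            raise ValueError(f"all-zero task column {lab}")
    return DesignMatrix(matrix=matrix, labels=labels, tr_s=schedule.tr_s)
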