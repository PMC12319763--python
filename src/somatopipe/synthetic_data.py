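"""Geometric phantom atlas and multi-subject block-design BOLD simulation.

The phantom stands in for the somatosensory pathway: small adjacent nuclei
in the medulla (cuneate for the hands, spinal trigeminal for the face),
their thalamic relays (VPL for the body, VPM for the face), and the S1
hand and face areas. Simulated data have the statistical structure the
analysis chain assumes: condition-specific multivoxel patterns that are
partially shared across subjects and spatially overlapping between
adjacent nuclei, an SNR gradient S1 >> thalamus > brainstem, physiological
noise (cardiac ~1 Hz, respiratory ~0.3 Hz), slow drift, and thermal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from somatopipe import design as _design


class GeometryError(ValueError):
    """Phantom geometry violates an atlas invariant."""


# --- Volume grid --------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel grid: world = origin + index * voxel_size."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError("all shape entries must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("all voxel sizes must be positive")

    @classmethod
    def centered(cls, shape=(40, 40, 40), voxel_size_mm=1.0) -> "VolumeGrid":
        """Grid whose voxel centres are symmetric about the world origin."""
        shape = tuple(int(s) for s in np.broadcast_to(shape, 3))
        vs = tuple(float(v) for v in np.broadcast_to(voxel_size_mm, 3))
        origin = tuple(-(s - 1) * v / 2.0 for s, v in zip(shape, vs))
        return cls(shape=shape, voxel_size_mm=vs, origin_mm=origin)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a]
            for a in range(3)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def is_mirror_symmetric(self) -> bool:
        """True if flipping index axis 0 maps voxel x-coordinates to their
        negatives (required to build mirrored left/right masks)."""
        x = self.coordinate_axes()[0]
        return bool(np.allclose(x, -x[::-1]))


# --- Phantom atlas ------------------------------------------------------------

Box = tuple[float, float, float, float, float, float]  # xmin,xmax,ymin,ymax,zmin,zmax

#: Default phantom geometry in mm (x: left < 0 < right; z: inferior to superior).
#: Left-side nuclei are listed; right-side counterparts are index mirrors.
DEFAULT_GEOMETRY: dict[str, Box] = {
    # parent regions
    "brainstem": (-8.0, 8.0, -8.0, 8.0, -20.0, -6.0),
    "thalamus": (-12.0, 12.0, -8.0, 8.0, -4.0, 6.0),
    "s1": (-16.0, 16.0, -6.0, 6.0, 8.0, 18.0),
    # brainstem nuclei: cuneate medial, spinal trigeminal directly lateral
    "left_cuneate": (-3.6, 0.0, -2.0, 2.0, -16.0, -9.0),
    "spinal_trigeminal_left": (-7.2, -3.6, -2.0, 2.0, -16.0, -9.0),
    # thalamic nuclei: VPM medial (bilateral), VPL lateral
    "vpm": (-3.6, 3.6, -2.0, 2.0, -2.0, 3.0),
    "vpl_left": (-9.0, -3.6, -2.0, 2.0, -2.0, 3.0),
    # S1 subregions
    "s1_face": (-5.0, 5.0, -4.0, 4.0, 10.0, 16.0),
    "s1_hand_left": (-14.0, -7.0, -4.0, 4.0, 10.0, 16.0),
}

MIRRORED = {
    "left_cuneate": "right_cuneate",
    "spinal_trigeminal_left": "spinal_trigeminal_right",
    "vpl_left": "vpl_right",
    "s1_hand_left": "s1_hand_right",
}

PARENTS = {
    "left_cuneate": "brainstem", "right_cuneate": "brainstem",
    "spinal_trigeminal_left": "brainstem", "spinal_trigeminal_right": "brainstem",
    "vpl_left": "thalamus", "vpl_right": "thalamus", "vpm": "thalamus",
    "s1_hand_left": "s1", "s1_hand_right": "s1", "s1_face": "s1",
}

#: Nucleus pairs required to touch (share at least one face-adjacent voxel pair)
ADJACENCY = [
    ("left_cuneate", "spinal_trigeminal_left"),
    ("right_cuneate", "spinal_trigeminal_right"),
    ("vpl_left", "vpm"),
    ("vpl_right", "vpm"),
]

REGION_NAMES = ("brainstem", "thalamus", "s1")
NUCLEUS_NAMES = tuple(PARENTS)


@dataclass
class PhantomAtlas:
    """Named boolean masks on a shared grid, with nucleus adjacency metadata."""

    grid: VolumeGrid
    masks: dict[str, np.ndarray]
    adjacency: list[tuple[str, str]] = field(default_factory=lambda: list(ADJACENCY))
    parents: dict[str, str] = field(default_factory=lambda: dict(PARENTS))

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]

    def region_of(self, name: str) -> str:
        return self.parents.get(name, name)

    def brain_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for r in REGION_NAMES:
            out |= self.masks[r]
        return out


def _box_mask(grid: VolumeGrid, box: Box) -> np.ndarray:
    ax = grid.coordinate_axes()
    mx = (ax[0] >= box[0]) & (ax[0] < box[1])
    my = (ax[1] >= box[2]) & (ax[1] < box[3])
    mz = (ax[2] >= box[4]) & (ax[2] < box[5])
    return mx[:, None, None] & my[None, :, None] & mz[None, None, :]


def count_face_adjacent_pairs(mask_a: np.ndarray, mask_b: np.ndarray) -> int:
    """Number of 6-neighbour voxel pairs with one voxel in each mask."""
    count = 0
    for axis in range(3):
        a_lead = np.take(mask_a, range(1, mask_a.shape[axis]), axis=axis)
        b_trail = np.take(mask_b, range(0, mask_b.shape[axis] - 1), axis=axis)
        count += int(np.sum(a_lead & b_trail))
        b_lead = np.take(mask_b, range(1, mask_b.shape[axis]), axis=axis)
        a_trail = np.take(mask_a, range(0, mask_a.shape[axis] - 1), axis=axis)
        count += int(np.sum(b_lead & a_trail))
    return count


def build_phantom_atlas(
    grid: VolumeGrid | None = None,
    geometry: dict[str, Box] | None = None,
) -> PhantomAtlas:
    """Construct the phantom atlas and validate every invariant.

    Nuclei are small boxes (a few mm across, as the real nuclei are only a
    few millimetres wide); right-hemisphere nuclei are exact index mirrors
    of the left ones, so the grid must be mirror-symmetric about x = 0.
    """
    if grid is None:
        grid = VolumeGrid.centered()
    geo = dict(DEFAULT_GEOMETRY)
    if geometry:
        geo.update(geometry)
    if not grid.is_mirror_symmetric():
        raise GeometryError("grid is not mirror-symmetric about x = 0")

    masks: dict[str, np.ndarray] = {}
    for name, box in geo.items():
        masks[name] = _box_mask(grid, box)
    for left, right in MIRRORED.items():
        masks[right] = masks[left][::-1].copy()

    for name in (*REGION_NAMES, *NUCLEUS_NAMES):
        if not masks[name].any():
            raise GeometryError(f"mask {name!r} is empty on this grid")
    for name, parent in PARENTS.items():
        if np.any(masks[name] & ~masks[parent]):
            raise GeometryError(f"nucleus {name!r} extends outside {parent!r}")
    nuclei = list(NUCLEUS_NAMES)
    for i, a in enumerate(nuclei):
        for b in nuclei[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise GeometryError(f"nucleus masks {a!r} and {b!r} overlap")
    for a, b in ADJACENCY:
        if count_face_adjacent_pairs(masks[a], masks[b]) < 1:
            raise GeometryError(f"masks {a!r} and {b!r} are not adjacent")
    return PhantomAtlas(grid=grid, masks=masks)


# --- Effect specification and wiring -----------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """Signal structure of the simulation.

    ``snr_*`` are per-region ratios of task response amplitude to thermal
    noise standard deviation; the default ordering S1 >> thalamus >
    brainstem mirrors the signal quality gradient of subcortical fMRI.
    ``pattern_overlap`` is the fraction of a nucleus's active voxels that
    its adjacent nucleus's condition also activates. ``amplitude`` is the
    injected canonical regression coefficient: the GLM beta an active voxel
    should recover, in signal units on a baseline of 100 per unit of the
    convolved canonical regressor. ``subject_variability`` is the sd of the
    per-subject multiplicative and additive perturbation of the template
    pattern; at 1.0 the subject-specific pattern component is as strong as
    the shared one, which is what keeps across-subject decoding of the
    noisier regions well below ceiling.
    """

    snr_s1: float = 0.5
    snr_thalamus: float = 0.16
    snr_brainstem: float = 0.05
    pattern_overlap: float = 0.3
    subject_variability: float = 1.0
    amplitude: float = 1.0
    active_fraction: float = 0.7

    def __post_init__(self):
        if min(self.snr_s1, self.snr_thalamus, self.snr_brainstem) <= 0:
            raise ValueError("SNRs must be positive")
        if not 0.0 <= self.pattern_overlap <= 1.0:
            raise ValueError("pattern_overlap must lie in [0, 1]")
        if self.subject_variability < 0:
            raise ValueError("subject_variability must be >= 0")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in (0, 1]")

    def snr_of(self, region: str) -> float:
        return {"s1": self.snr_s1, "thalamus": self.snr_thalamus,
                "brainstem": self.snr_brainstem}[region]


#: Laterality wiring: hand movement drives the ipsilateral dorsal-column
#: nucleus (cuneate) but the contralateral thalamic and cortical relays;
#: face movement drives the trigeminal pathway bilaterally.
DEFAULT_WIRING: dict[str, tuple[str, ...]] = {
    "left_hand": ("left_cuneate", "vpl_right", "s1_hand_right"),
    "right_hand": ("right_cuneate", "vpl_left", "s1_hand_left"),
    "face": ("spinal_trigeminal_left", "spinal_trigeminal_right",
             "vpm", "s1_face"),
}


def _home_conditions(wiring: dict[str, tuple[str, ...]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for cond, nuclei in wiring.items():
        for n in nuclei:
            out[n] = cond
    return out


@dataclass
class ConditionPatterns:
    """Template and per-subject condition amplitude maps (percent signal change)."""

    templates: dict[str, np.ndarray]
    subjects: list[dict[str, np.ndarray]]
    wiring: dict[str, tuple[str, ...]]


def make_condition_patterns(
    atlas: PhantomAtlas,
    effect: EffectSpec,
    seed: int,
    n_subjects: int = 1,
    wiring: dict[str, tuple[str, ...]] | None = None,
) -> ConditionPatterns:
    """Template condition patterns plus per-subject perturbed copies.

    Each condition's template is supported on its wired nuclei: a fraction
    ``effect.active_fraction`` of each nucleus's voxels receive amplitudes
    drawn around ``effect.amplitude``. For every adjacent nucleus pair, a
    fraction ``effect.pattern_overlap`` of the home condition's active
    voxels is additionally activated by the neighbour's condition (with an
    independent amplitude pattern), so univariate separation degrades with
    overlap while multivariate pattern geometry is preserved. Per-subject
    maps are ``template * (1 + N(0, sv))`` plus additive Gaussian noise of
    sd ``sv * amplitude`` on the support.
    """
    wiring = dict(wiring or DEFAULT_WIRING)
    rng = np.random.default_rng([int(seed), 0x5EED])
    shape = atlas.grid.shape
    conditions = list(wiring)
    templates = {c: np.zeros(shape) for c in conditions}
    home = _home_conditions(wiring)

    def draw_amplitudes(n: int) -> np.ndarray:
        return effect.amplitude * rng.uniform(0.5, 1.5, size=n)

    active_sets: dict[str, np.ndarray] = {}  # nucleus -> flat active indices
    for cond in conditions:
        flat = templates[cond].reshape(-1)
        for nucleus in wiring[cond]:
            vox = np.flatnonzero(atlas.mask(nucleus).reshape(-1))
            k = max(1, int(round(effect.active_fraction * len(vox))))
            chosen = rng.choice(vox, size=k, replace=False)
            flat[chosen] = draw_amplitudes(k)
            active_sets[nucleus] = chosen

    # cross-activation between adjacent nuclei
    for a, b in atlas.adjacency:
        for own, other in ((a, b), (b, a)):
            cond_own, cond_other = home.get(own), home.get(other)
            if cond_own is None or cond_other is None or cond_own == cond_other:
                continue
            active = active_sets.get(own)
            if active is None:
                continue
            k = int(round(effect.pattern_overlap * len(active)))
            if k == 0:
                continue
            shared = rng.choice(active, size=k, replace=False)
            templates[cond_other].reshape(-1)[shared] = draw_amplitudes(k)

    subjects: list[dict[str, np.ndarray]] = []
    sv = effect.subject_variability
    for s in range(n_subjects):
        srng = np.random.default_rng([int(seed), 0x5EED, s + 1])
        maps: dict[str, np.ndarray] = {}
        for cond in conditions:
            tpl = templates[cond]
            support = tpl != 0
            gain = 1.0 + sv * srng.standard_normal(shape)
            add = sv * effect.amplitude * srng.standard_normal(shape)
            maps[cond] = tpl * gain + add * support
        subjects.append(maps)
    return ConditionPatterns(templates=templates, subjects=subjects,
                             wiring=wiring)


# --- Physiological trace simulation -------------------------------------------


@dataclass
class PhysioTrace:
    """Cardiac peak times plus a sampled respiratory waveform."""

    cardiac_peak_times_s: np.ndarray
    respiratory_waveform: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        peaks = np.asarray(self.cardiac_peak_times_s, dtype=float)
        if peaks.ndim != 1 or np.any(np.diff(peaks) <= 0):
            raise ValueError("cardiac peak times must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


def simulate_physio(
    duration_s: float,
    cardiac_rate_hz: float = 1.0,
    resp_rate_hz: float = 0.3,
    jitter: float = 0.05,
    seed: int = 0,
    sampling_rate_hz: float = 100.0,
) -> PhysioTrace:
    """Simulate a cardiac peak train and respiratory bellows waveform.

    Cardiac inter-peak intervals are jittered around ``1/cardiac_rate_hz``;
    the respiratory waveform is a sinusoid with jittered instantaneous
    frequency. ``jitter`` is the fractional sd of both perturbations;
    zero jitter gives exactly periodic traces.
    """
    if duration_s <= 0 or cardiac_rate_hz <= 0 or resp_rate_hz <= 0:
        raise ValueError("duration and rates must be positive")
    rng = np.random.default_rng([int(seed), 0xCA4D])
    mean_ibi = 1.0 / cardiac_rate_hz
    n_max = int(np.ceil(duration_s / mean_ibi)) + 8
    intervals = mean_ibi * np.clip(
        1.0 + jitter * rng.standard_normal(n_max), 0.2, 5.0)
    peaks = np.concatenate([[0.0], np.cumsum(intervals)])
    peaks = peaks[peaks <= duration_s]

    n_samp = int(duration_s * sampling_rate_hz)
    t = np.arange(n_samp) / sampling_rate_hz
    if jitter > 0:
        # slowly varying instantaneous frequency: smooth noise at ~0.05 Hz
        n_knots = max(int(duration_s * 0.05) + 2, 4)
        knots_t = np.linspace(0, duration_s, n_knots)
        knots_f = resp_rate_hz * (1.0 + jitter * rng.standard_normal(n_knots))
        freq = np.interp(t, knots_t, np.clip(knots_f, 0.05 * resp_rate_hz, None))
    else:
        freq = np.full(n_samp, resp_rate_hz)
    phase = 2 * np.pi * np.cumsum(freq) / sampling_rate_hz
    waveform = np.sin(phase)
    return PhysioTrace(cardiac_peak_times_s=peaks,
                       respiratory_waveform=waveform,
                       sampling_rate_hz=sampling_rate_hz)


# --- Run and cohort simulation ------------------------------------------------


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise components, in percent-signal-change units of a
    baseline of 100."""

    baseline: float = 100.0
    cardiac_amplitude: float = 0.4
    respiratory_amplitude: float = 0.4
    drift_linear_amplitude: float = 0.5
    drift_cosine_amplitude: float = 0.3
    drift_period_s: float = 300.0
    thermal: bool = True
    background_region: str = "brainstem"  # SNR used outside named regions


@dataclass
class RunData:
    image: np.ndarray  # (x, y, z, t)
    schedule: _design.BlockSchedule
    physio: PhysioTrace
    mean_abs_displacement_mm: float


@dataclass
class SubjectDataset:
    """One simulated participant: runs plus per-condition ground truth."""

    subject_id: str
    runs: list[RunData]
    ground_truth: dict[str, np.ndarray]
    grid: VolumeGrid

    def __post_init__(self):
        for r in self.runs:
            if r.image.shape[:3] != self.grid.shape:
                raise ValueError("all runs must share the dataset grid")
            if r.image.shape[3] != r.schedule.n_volumes:
                raise ValueError("run length must match schedule volume count")


def _noise_sd_map(atlas: PhantomAtlas, effect: EffectSpec,
                  background_region: str) -> np.ndarray:
    sd = np.full(atlas.grid.shape,
                 effect.amplitude / effect.snr_of(background_region))
    for region in REGION_NAMES:
        sd[atlas.mask(region)] = effect.amplitude / effect.snr_of(region)
    return sd


def simulate_run(
    patterns: dict[str, np.ndarray],
    schedule: _design.BlockSchedule,
    physio_trace: PhysioTrace,
    noise: NoiseConfig,
    seed: int,
    atlas: PhantomAtlas,
    effect: EffectSpec,
    basis: _design.HRFBasis | None = None,
) -> np.ndarray:
    """Simulate one 4-D BOLD run.

    Signal: per-condition amplitude maps (percent signal change on a
    baseline of 100) times the condition boxcar convolved with the
    canonical HRF. Added noise: thermal Gaussian noise scaled per region
    by the EffectSpec SNR, cardiac and respiratory sinusoids of the
    instantaneous physiological phase with random voxelwise phase and
    gain, and linear plus slow-cosine drift.
    """
    from somatopipe.physio import phase_series

    grid = atlas.grid
    for cond, m in patterns.items():
        if m.shape != grid.shape:
            raise ValueError(
                f"pattern for {cond!r} has shape {m.shape}, grid is {grid.shape}")
    if basis is None:
        basis = _design.hrf_basis(schedule.tr_s)
    regs = _design.condition_regressors(schedule, basis)

    rng = np.random.default_rng([int(seed), 0xB01D])
    nvox = grid.n_voxels
    nt = schedule.n_volumes
    data = np.full((nvox, nt), noise.baseline)
    for cond, amp_map in patterns.items():
        canonical = regs[cond][0]  # unit-peak canonical regressor
        data += amp_map.reshape(-1, 1) * canonical[None, :]

    t_vol = (np.arange(nt) + 0.5) * schedule.tr_s
    if noise.cardiac_amplitude > 0 or noise.respiratory_amplitude > 0:
        ph = phase_series(physio_trace, t_vol)
        for amp, phase in ((noise.cardiac_amplitude, ph.cardiac),
                           (noise.respiratory_amplitude, ph.respiratory)):
            if amp <= 0:
                continue
            gain = amp * rng.uniform(0.5, 1.5, size=nvox)
            theta = rng.uniform(0, 2 * np.pi, size=nvox)
            data += gain[:, None] * np.sin(phase[None, :] + theta[:, None])

    if noise.drift_linear_amplitude > 0:
        slope = noise.drift_linear_amplitude * rng.standard_normal(nvox)
        tt = (t_vol - t_vol.mean()) / (t_vol[-1] - t_vol[0] + 1e-12)
        data += slope[:, None] * tt[None, :]
    if noise.drift_cosine_amplitude > 0:
        amp = noise.drift_cosine_amplitude * rng.standard_normal(nvox)
        phi = rng.uniform(0, 2 * np.pi, size=nvox)
        data += amp[:, None] * np.cos(
            2 * np.pi * t_vol[None, :] / noise.drift_period_s + phi[:, None])

    if noise.thermal:
        sd = _noise_sd_map(atlas, effect, noise.background_region).reshape(-1)
        data += sd[:, None] * rng.standard_normal((nvox, nt))

    return data.reshape(*grid.shape, nt)


@dataclass(frozen=True)
class DisplacementModel:
    """Per-run mean absolute displacement draw (mm); gamma-distributed by
    default so that roughly 5% of runs exceed the 1 mm exclusion threshold."""

    shape: float = 2.0
    scale: float = 0.22

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))


def generate_cohort(
    n_subjects: int = 20,
    atlas: PhantomAtlas | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
    n_runs: int = 4,
    noise: NoiseConfig | None = None,
    displacement: DisplacementModel | None = None,
    tr_s: float = _design.DEFAULT_TR_S,
    n_volumes: int = _design.DEFAULT_N_VOLUMES,
    blocks_per_condition: int = _design.BLOCKS_PER_CONDITION,
    wiring: dict[str, tuple[str, ...]] | None = None,
) -> list[SubjectDataset]:
    """Simulate a cohort of subjects, each with ``n_runs`` runs."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if atlas is None:
        atlas = build_phantom_atlas()
    effect = effect or EffectSpec()
    noise = noise or NoiseConfig()
    displacement = displacement or DisplacementModel()

    patterns = make_condition_patterns(atlas, effect, seed,
                                       n_subjects=n_subjects, wiring=wiring)
    basis = _design.hrf_basis(tr_s)
    cohort: list[SubjectDataset] = []
    for s in range(n_subjects):
        rng = np.random.default_rng([int(seed), 0xC040, s])
        runs: list[RunData] = []
        schedules = _design.make_run_schedules(
            n_runs, order_seed=int(seed) * 1_000 + s,
            tr_s=tr_s, n_volumes=n_volumes,
            blocks_per_condition=blocks_per_condition)
        for r, sched in enumerate(schedules):
            run_seed = int(rng.integers(0, 2**31 - 1))
            trace = simulate_physio(sched.duration_s, seed=run_seed)
            image = simulate_run(patterns.subjects[s], sched, trace, noise,
                                 seed=run_seed, atlas=atlas, effect=effect,
                                 basis=basis).astype(np.float32)
            disp = displacement.draw(rng)
            runs.append(RunData(image=image, schedule=sched, physio=trace,
                                mean_abs_displacement_mm=disp))
        cohort.append(SubjectDataset(
            subject_id=f"sub-{s + 1:02d}", runs=runs,
            ground_truth=patterns.subjects[s], grid=atlas.grid))
    return cohort
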