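"""Synthetic dyadic task schedules, paired BOLD runs and behaviour tables.

The generator emulates the study conditions of a dual-scanner
joint-attention experiment: 5 s trials (2 s of mutual eye contact, a 2.5 s
ball cue, a 0.5 s blank), three identical trials per 15 s block, TR = 3 s,
85 volumes per run with the first five discarded, and six runs (three
concordant, three discordant) per participant. A run comes in two flavours:
in concordant runs both partners attend the same target (conditions ES/BS
plus the simultaneous-ball control SBNc); in discordant runs the cued
partner looks away from the target (EN/BN, control SBNd). The two
partners' event tables always cover identical trial onsets with
complementary labels — a cue shown to P is an eye cue from Q's side.

Paired runs optionally share a band-limited latent signal confined to the
"IFG_seed" region: for a coupling (shared-variance fraction) ``c`` each ROI
voxel's noise is sqrt(1-c)·own + sqrt(c)·shared, so the expected
inter-brain voxel correlation of the noise inside the ROI equals ``c``
while everything outside stays independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from dyadscan.core import BoldRun, DyadscanError
from dyadscan.glm import canonical_hrf

__all__ = [
    "TaskSchedule",
    "SimulationConfig",
    "simulate_task_schedule",
    "schedule_from_events",
    "simulate_dyad_bold",
    "simulate_behavior",
    "simulate_coupled_residuals",
    "simulate_connected_residuals",
    "band_limited_noise",
    "ar1_noise",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_ACCURACY_MEANS",
    "DEFAULT_ACCURACY_EFFECTS",
]

# Trial geometry (seconds)
TRIAL_S = 5.0
EC_S = 2.0
CUE_S = 2.5
BLANK_S = 0.5
BLOCK_S = 15.0
TRIALS_PER_BLOCK = 3

TRIAL_KINDS = ("cue_to_p", "cue_to_q", "cue_to_both", "ec_only")


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

# Label maps: trial kind -> (label for P, label for Q)
_LABELS = {
    "concordant": {
        "cue_to_p": ("BS", "ES"),
        "cue_to_q": ("ES", "BS"),
        "cue_to_both": ("SBNc", "SBNc"),
        "ec_only": ("ec_only", "ec_only"),
    },
    "discordant": {
        "cue_to_p": ("BN", "EN"),
        "cue_to_q": ("EN", "BN"),
        "cue_to_both": ("SBNd", "SBNd"),
        "ec_only": ("ec_only", "ec_only"),
    },
}


@dataclass
class TaskSchedule:
    """Block schedule of one dyadic run.

    ``block_kinds`` lists one trial kind per 15 s block; each block holds
    three identical 5 s trials.
    """

    run_type: str
    block_kinds: list[str]

    def __post_init__(self) -> None:
        if self.run_type not in _LABELS:
            raise DyadscanError(f"unknown run type {self.run_type!r}")
        bad = sorted(set(self.block_kinds) - set(TRIAL_KINDS))
        if bad:
            raise DyadscanError(f"unknown trial kinds: {bad}")

    @property
    def duration(self) -> float:
        return len(self.block_kinds) * BLOCK_S

    @property
    def trials(self) -> list[tuple[float, str]]:
        out = []
        for b, kind in enumerate(self.block_kinds):
            for j in range(TRIALS_PER_BLOCK):
                out.append((b * BLOCK_S + j * TRIAL_S, kind))
        return out

    def event_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Per-partner event tables (onset, duration, trial_type).

        Event onset is the cue onset, 2 s into the trial; the modelled
        duration is the 2.5 s cue period. Eye-contact-only trials are
        emitted too (they carry the baseline label ``ec_only``).
        """
        rows_p, rows_q = [], []
        labels = _LABELS[self.run_type]
        for onset, kind in self.trials:
            lab_p, lab_q = labels[kind]
            rows_p.append((onset + EC_S, CUE_S, lab_p))
            rows_q.append((onset + EC_S, CUE_S, lab_q))
        cols = ["onset", "duration", "trial_type"]
        return (
            pd.DataFrame(rows_p, columns=cols),
            pd.DataFrame(rows_q, columns=cols),
        )


def _default_effect_sizes() -> dict[str, dict[str, float]]:
    # Eye-cued conditions drive gaze-processing regions (OP, STS); every
    # cued condition carries a common visual response in OP.
    return {
        "ES": {"OP": 1.0, "STS": 0.5},
        "EN": {"OP": 1.0, "STS": 0.5},
        "BS": {"OP": 0.5},
        "BN": {"OP": 0.5},
        "SBNc": {"OP": 0.5},
        "SBNd": {"OP": 0.5},
    }


@dataclass
class SimulationConfig:
    """Parameters of the dyadic BOLD generator.

    Defaults mirror the acquisition bookkeeping of the emulated study:
    TR = 3 s, 85 volumes per run of which the first 5 are discarded, six
    runs per subject. ``coupling`` is the shared-variance fraction of the
    pair latent inside the "IFG_seed" ROI; 0 disables coupling while
    leaving every other random draw unchanged (same generator streams).
    """

    shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 4.0
    tr: float = 3.0
    volumes_per_run: int = 85
    discard_leading: int = 5
    n_runs: int = 6
    ar_rho: float = 0.3
    drift_amplitude: float = 1.0
    drift_period: float = 256.0
    noise_sd: float = 1.0
    coupling: float = 0.0
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=_default_effect_sizes
    )
    #: Brief evoked response at every 15 s block boundary (condition
    #: switch), confined to the task-visual "OP" ROI and absent from the
    #: condition regressors. This emulates the incomplete removal of the
    #: task effect from residual data: the block lattice puts its
    #: fundamental at exactly 1/15 ~ 0.067 Hz.
    block_transient_amp: float = 0.5
    block_transient_duration: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise DyadscanError("coupling must lie in [0, 1]")
        if not 0.0 <= self.ar_rho < 1.0:
            raise DyadscanError("ar_rho must lie in [0, 1)")
        if self.discard_leading >= self.volumes_per_run:
            raise DyadscanError("discard_leading must be < volumes_per_run")

    @property
    def retained_per_run(self) -> int:
        return self.volumes_per_run - self.discard_leading

    @property
    def retained_total(self) -> int:
        return self.n_runs * self.retained_per_run

    @property
    def task_duration(self) -> float:
        """Scheduled task duration of one run: the retained volumes."""
        return self.retained_per_run * self.tr

    def roi_masks(self) -> dict[str, np.ndarray]:
        """Disjoint box ROIs scaled to the grid: the inter-brain coupling
        seed ("IFG_seed"), an early-visual region ("OP") and a gaze-
        integration region ("STS")."""
        nx, ny, nz = self.shape

        def box(fx0, fx1, fy0, fy1, fz0, fz1):
            m = np.zeros(self.shape, dtype=bool)
            sl = [
                slice(max(0, int(fx0 * nx)), max(1, int(np.ceil(fx1 * nx)))),
                slice(max(0, int(fy0 * ny)), max(1, int(np.ceil(fy1 * ny)))),
                slice(max(0, int(fz0 * nz)), max(1, int(np.ceil(fz1 * nz)))),
            ]
            m[tuple(sl)] = True
            return m

        # OP is separated from the other two along x; IFG and STS share x
        # but are separated along y, so the boxes stay disjoint down to
        # very small grids.
        masks = {
            "OP": box(0.05, 0.45, 0.05, 0.45, 0.30, 0.70),
            "IFG_seed": box(0.55, 0.95, 0.55, 0.95, 0.30, 0.70),
            "STS": box(0.55, 0.95, 0.05, 0.45, 0.30, 0.70),
        }
        ifg, op, sts = masks["IFG_seed"], masks["OP"], masks["STS"]
        if (ifg & op).any() or (ifg & sts).any() or (op & sts).any():
            raise DyadscanError("grid too small for disjoint ROIs")
        return masks

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff


def simulate_task_schedule(
    config: SimulationConfig, run_type: str, seed
) -> TaskSchedule:
    """Randomised block schedule for one run.

    The run's task duration must divide into whole 15 s blocks. Block
    kinds are balanced (as evenly as the block count allows over the four
    trial kinds) and shuffled under the given seed.
    """
    if run_type not in _LABELS:
        raise DyadscanError(f"unknown run type {run_type!r}")
    dur = config.task_duration
    n_blocks = dur / BLOCK_S
    if abs(n_blocks - round(n_blocks)) > 1e-9:
        raise DyadscanError(
            f"run duration {dur} s is not a multiple of the {BLOCK_S} s block"
        )
    n_blocks = int(round(n_blocks))
    rng = np.random.default_rng(seed)
    base = n_blocks // len(TRIAL_KINDS)
    kinds = list(TRIAL_KINDS) * base
    extra = n_blocks - len(kinds)
    if extra:
        kinds += list(rng.choice(TRIAL_KINDS, size=extra, replace=False))
    order = rng.permutation(len(kinds))
    return TaskSchedule(run_type=run_type, block_kinds=[kinds[i] for i in order])


def schedule_from_events(
    events_p: pd.DataFrame, events_q: pd.DataFrame
) -> TaskSchedule:
    """Re-derive the block schedule from a pair of emitted event tables
    (the inverse of :meth:`TaskSchedule.event_tables`)."""
    if len(events_p) != len(events_q):
        raise DyadscanError("partner event tables differ in length")
    labels = set(events_p["trial_type"]) | set(events_q["trial_type"])
    if labels & {"ES", "BS", "SBNc"}:
        run_type = "concordant"
    elif labels & {"EN", "BN", "SBNd"}:
        run_type = "discordant"
    else:
        run_type = "concordant"  # pure eye-contact run: flavour irrelevant
    inverse = {
        (lp, lq): kind for kind, (lp, lq) in _LABELS[run_type].items()
    }
    ep = events_p.sort_values("onset").reset_index(drop=True)
    eq = events_q.sort_values("onset").reset_index(drop=True)
    kinds = []
    for (_, rp), (_, rq) in zip(ep.iterrows(), eq.iterrows()):
        key = (rp["trial_type"], rq["trial_type"])
        if key not in inverse:
            raise DyadscanError(f"labels {key} are not complementary")
        kinds.append(inverse[key])
        trial_onset = rp["onset"] - EC_S
        if abs(trial_onset % TRIAL_S) > 1e-6 and abs(trial_onset % TRIAL_S - TRIAL_S) > 1e-6:
            raise DyadscanError("event onsets do not sit on the trial grid")
    if len(kinds) % TRIALS_PER_BLOCK:
        raise DyadscanError("trial count is not a whole number of blocks")
    block_kinds = []
    for b in range(0, len(kinds), TRIALS_PER_BLOCK):
        block = kinds[b : b + TRIALS_PER_BLOCK]
        if len(set(block)) != 1:
            raise DyadscanError("blocks must repeat one condition three times")
        block_kinds.append(block[0])
    return TaskSchedule(run_type=run_type, block_kinds=block_kinds)


def band_limited_noise(
    n: int, tr: float, rng, low: float = 0.01, high: float = 0.06, size=None
) -> np.ndarray:
    """Unit-variance noise with power confined to [low, high] Hz.

    Built in the frequency domain so the band is exact; this is the shape
    of the pair-shared latent signal, chosen to survive the 0.01-0.06 Hz
    connectivity band-pass downstream. With ``size`` an int, returns a
    (size, n) array of independent draws.
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    if not keep.any():
        raise DyadscanError("series too short for the requested band")
    m = int(keep.sum())
    rows = 1 if size is None else int(size)
    spec = np.zeros((rows, len(freqs)), dtype=complex)
    spec[:, keep] = rng.normal(size=(rows, m)) + 1j * rng.normal(size=(rows, m))
    x = np.fft.irfft(spec, n=n, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DyadscanError("degenerate band-limited draw")
    x = x / sd
    return x[0] if size is None else x


def ar1_noise(shape, rho: float, rng, sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``.

    ``shape`` is (T,) or (T, V); time runs along axis 0.
    """
    burn = 100
    if np.isscalar(shape):
        shape = (int(shape),)
    full = (shape[0] + burn,) + tuple(shape[1:])
    eps = rng.normal(size=full)
    x = signal.lfilter([1.0], [1.0, -rho], eps, axis=0)
    x = x[burn:]
    return x * (sd * np.sqrt(1.0 - rho**2))


def _condition_regressors(
    events: pd.DataFrame, config: SimulationConfig, offset: float
) -> dict[str, np.ndarray]:
    """HRF-convolved boxcars over the FULL run (all volumes_per_run
    samples); ``offset`` shifts scheduled onsets into scanner time."""
    oversampling = 16
    dt = config.tr / oversampling
    n_hi = config.volumes_per_run * oversampling
    hrf = canonical_hrf(config.tr, oversampling=oversampling)
    sample_idx = np.arange(config.volumes_per_run) * oversampling
    out: dict[str, np.ndarray] = {}
    for cond, grp in events.groupby("trial_type"):
        box = np.zeros(n_hi)
        for _, row in grp.iterrows():
            i0 = int(round((row["onset"] + offset) / dt))
            i1 = int(round((row["onset"] + offset + row["duration"]) / dt))
            box[i0 : min(i1, n_hi)] = 1.0
        out[cond] = np.convolve(box, hrf)[:n_hi][sample_idx]
    return out


def _block_transient_regressor(config: SimulationConfig, offset: float) -> np.ndarray:
    """HRF response to a short stimulus at every 15 s block onset."""
    oversampling = 16
    dt = config.tr / oversampling
    n_hi = config.volumes_per_run * oversampling
    hrf = canonical_hrf(config.tr, oversampling=oversampling)
    box = np.zeros(n_hi)
    n_blocks = int((config.volumes_per_run * config.tr - offset) // BLOCK_S)
    for b in range(n_blocks):
        i0 = int(round((offset + b * BLOCK_S) / dt))
        i1 = int(round((offset + b * BLOCK_S + config.block_transient_duration) / dt))
        box[i0 : min(i1, n_hi)] = 1.0
    reg = np.convolve(box, hrf)[:n_hi]
    return reg[np.arange(config.volumes_per_run) * oversampling]


def _beta_volume(config: SimulationConfig, cond: str, masks) -> np.ndarray:
    beta = np.zeros(config.shape)
    for roi, amp in config.effect_sizes.get(cond, {}).items():
        beta[masks[roi]] += amp
    return beta


def simulate_dyad_bold(
    schedule_p: TaskSchedule,
    schedule_q: TaskSchedule,
    config: SimulationConfig,
    paired: bool,
    seed,
) -> tuple[BoldRun, BoldRun]:
    """Generate one paired BOLD run for both partners.

    Signal model per voxel: sum over conditions of beta x (boxcar * HRF),
    plus a slow cosine drift, plus stationary AR(1) noise. Iff ``paired``,
    voxels inside the "IFG_seed" ROI replace a fraction of their noise
    variance by a band-limited latent series common to both partners. The
    scheduled task starts after the discarded leading volumes.

    The three generator streams (pair latent, subject P, subject Q) are
    spawned from ``seed``, so setting coupling to 0 changes nothing
    outside the coupling term.
    """
    if schedule_p.run_type != schedule_q.run_type:
        raise DyadscanError("partners must share one run type")
    ss = _seedseq(seed)
    rng_pair, rng_p, rng_q = [np.random.default_rng(s) for s in ss.spawn(3)]
    shared = band_limited_noise(config.volumes_per_run, config.tr, rng_pair)
    masks = config.roi_masks()
    c = config.coupling

    runs = []
    for schedule, own_events_idx, rng in (
        (schedule_p, 0, rng_p),
        (schedule_q, 1, rng_q),
    ):
        events = schedule.event_tables()[own_events_idx]
        offset = config.discard_leading * config.tr
        regs = _condition_regressors(events, config, offset)
        t_len = config.volumes_per_run
        vol = np.zeros(config.shape + (t_len,))
        for cond, reg in regs.items():
            if cond == "ec_only":
                continue  # baseline state carries no evoked response
            beta = _beta_volume(config, cond, masks)
            vol += beta[..., None] * reg[None, None, None, :]
        if config.block_transient_amp:
            trans = _block_transient_regressor(config, offset)
            vol[masks["OP"]] += config.block_transient_amp * trans[None, :]
        t = np.arange(t_len) * config.tr
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amplitude * np.cos(
            2 * np.pi * t / config.drift_period + phase
        )
        vol += drift[None, None, None, :]
        n_vox = int(np.prod(config.shape))
        noise = ar1_noise((t_len, n_vox), config.ar_rho, rng, sd=config.noise_sd)
        noise = noise.T.reshape(config.shape + (t_len,))
        if paired and c > 0:
            roi = masks["IFG_seed"]
            noise[roi] = (
                np.sqrt(1.0 - c) * noise[roi]
                + np.sqrt(c) * config.noise_sd * shared[None, :]
            )
        vol += noise
        runs.append(BoldRun(vol, tr=config.tr, affine=config.affine))
    return runs[0], runs[1]


# ---------------------------------------------------------------------------
# behaviour

DEFAULT_GROUP_SIZES = {
    "ASD": 21,
    "NormalPairedASD": 21,
    "Normal3T": 19,
    "Normal1.5T": 19,
}

TASK_CONDITIONS = ("ES", "EN", "BS", "BN")

#: Baseline accuracy per condition (near ceiling for ball cues, slightly
#: lower for eye cues, as gaze reading is the harder judgement).
DEFAULT_ACCURACY_MEANS = {"ES": 0.93, "EN": 0.91, "BS": 0.96, "BN": 0.95}

#: Group deficits, eye-cued conditions only: a clear deficit for the ASD
#: group, a small one for their typically-developed partners.
DEFAULT_ACCURACY_EFFECTS = {
    ("ASD", "ES"): -0.15,
    ("ASD", "EN"): -0.15,
    ("NormalPairedASD", "ES"): -0.04,
    ("NormalPairedASD", "EN"): -0.04,
}


def simulate_behavior(
    n_per_group: dict[str, int] | None = None,
    effects: dict[tuple[str, str], float] | None = None,
    noise_sd: float = 0.06,
    seed=None,
    baseline: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Accuracy table with the Group x Task structure of the paradigm.

    One row per subject x condition; accuracy is the cell mean plus
    Gaussian noise, clipped to [0, 1]. With the default effect
    specification the expected pattern is: ASD below the other groups in
    the eye-cued conditions (ES, EN) and no group differences in the
    ball-cued conditions (BS, BN).
    """
    n_per_group = dict(DEFAULT_GROUP_SIZES if n_per_group is None else n_per_group)
    effects = dict(DEFAULT_ACCURACY_EFFECTS if effects is None else effects)
    baseline = dict(DEFAULT_ACCURACY_MEANS if baseline is None else baseline)
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        for i in range(n):
            sid = f"{group}_{i:02d}"
            for cond in TASK_CONDITIONS:
                mu = baseline[cond] + effects.get((group, cond), 0.0)
                acc = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((sid, group, cond, float(np.clip(acc, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["subject", "group", "condition", "accuracy"])


def simulate_coupled_residuals(
    n_pairs: int,
    coupling: float,
    n_timepoints: int,
    seed=None,
    tr: float = 3.0,
    ar_rho: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-level shorthand for the paired-noise construction.

    Returns two (n_pairs, T) arrays: subject i of side A and subject i of
    side B were "scanned together" and share a band-limited latent with
    variance fraction ``coupling``; all other combinations are
    independent. This mirrors, series-for-series, what the full volume
    generator injects inside the coupled ROI, and is the economical route
    for Monte-Carlo calibration of the pair / pseudo-pair inference.
    """
    if not 0.0 <= coupling <= 1.0:
        raise DyadscanError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(_seedseq(seed))
    shared = band_limited_noise(n_timepoints, tr, rng, size=n_pairs)
    ea = ar1_noise((n_timepoints, n_pairs), ar_rho, rng).T
    eb = ar1_noise((n_timepoints, n_pairs), ar_rho, rng).T
    for e in (ea, eb):
        e -= e.mean(axis=1, keepdims=True)
        e /= e.std(axis=1, keepdims=True)
    a = np.sqrt(coupling) * shared + np.sqrt(1 - coupling) * ea
    b = np.sqrt(coupling) * shared + np.sqrt(1 - coupling) * eb
    return a, b


def simulate_connected_residuals(
    weights,
    config: SimulationConfig | None = None,
    n_timepoints: int = 468,
    latent_amp: float = 1.0,
    seed=None,
) -> list[np.ndarray]:
    """Residual-level intra-brain network generator.

    For each subject i a private band-limited latent drives the
    "IFG_seed" ROI with amplitude ``latent_amp`` and the "STS" ROI with
    amplitude ``weights[i] * latent_amp``, on top of unit-sd AR(1) noise
    everywhere — the generative picture behind the seed-to-voxel
    connectivity analysis, with a per-subject coupling scale. Returns one
    (X, Y, Z, T) residual-like array per subject.
    """
    config = config or SimulationConfig()
    masks = config.roi_masks()
    rng = np.random.default_rng(_seedseq(seed))
    out = []
    n_vox = int(np.prod(config.shape))
    for w in np.asarray(weights, dtype=float):
        g = band_limited_noise(n_timepoints, config.tr, rng)
        data = ar1_noise((n_timepoints, n_vox), config.ar_rho, rng).T
        data = data.reshape(config.shape + (n_timepoints,))
        data[masks["IFG_seed"]] += latent_amp * g[None, :]
        data[masks["STS"]] += w * latent_amp * g[None, :]
        out.append(data)
    return out
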