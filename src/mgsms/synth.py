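"""Synthetic memory-guided saccade (MGS) sessions with known ground truth.

Real recordings for this paradigm are not publicly deposited, so every
downstream stage is exercised on simulated sessions that emulate the study
design: 17 subjects x 120 trials, a 1 s fixation / 300 ms stimulus /
1.5-2.5 s memory / 1 s saccade trial structure, 12 target locations on two
eccentricity rings (6 and 12 degrees of visual angle), 20-channel 10-20 EEG,
and 1000 Hz monocular gaze.

The EEG generator plants a semi-Markov sequence over 8 polarity states
(A+/- ... D+/-) built from 4 canonical template topographies; each sample is
its state's map scaled by a half-sine amplitude envelope plus white noise.
Gaze traces fixate screen center until the go cue and then saccade to the
target with an isotropic Gaussian landing error whose per-trial spread can be
coupled to the *planted* number of D+ -> D- transitions in the memory window
— coupling to ground truth rather than to measured quantities keeps recovery
of the error/transition correlation a genuine test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import MONTAGE_20, montage_xy
from .segmentation import (
    MODE_8,
    STATES_4,
    STATES_8,
    LabelSequence,
    PrototypeSet,
    run_lengths,
)

EVENT_COLUMNS = (
    "subject",
    "trial",
    "t_fix_on_s",
    "t_stim_on_s",
    "t_stim_off_s",
    "t_go_s",
    "target_index",
    "target_x_deg",
    "target_y_deg",
    "eccentricity_deg",
)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TaskConfig:
    """Study-design parameters of the MGS task and recording setup."""

    n_subjects: int = 17
    n_trials: int = 120
    fix_dur: float = 1.0
    stim_dur: float = 0.3
    mem_dur_range: tuple[float, float] = (1.5, 2.5)
    sacc_dur: float = 1.0
    eccentricities: tuple[float, ...] = (6.0, 12.0)
    n_positions: int = 12
    fs_eeg: float = 250.0
    fs_gaze: float = 1000.0
    screen_px: tuple[int, int] = (1366, 768)
    px_per_deg: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fix_dur", "stim_dur", "sacc_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.mem_dur_range[0] <= self.mem_dur_range[1]):
            raise ValueError("mem_dur_range must be positive and ordered")
        if self.n_positions % len(self.eccentricities):
            raise ValueError("n_positions must divide evenly over eccentricities")
        if self.n_trials % self.n_positions:
            raise ValueError("n_trials must be a multiple of n_positions")

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.screen_px[0] / 2.0, self.screen_px[1] / 2.0)

    def target_grid_deg(self) -> np.ndarray:
        """(n_positions, 3) array of target (x_deg, y_deg, eccentricity).

        Positions are spread evenly in angle on each eccentricity ring, with
        alternate rings offset by half a step so the 12 locations do not
        overlap radially.
        """
        per_ring = self.n_positions // len(self.eccentricities)
        rows = []
        for r, ecc in enumerate(self.eccentricities):
            ang = 2 * np.pi * (np.arange(per_ring) + 0.5 * (r % 2)) / per_ring
            for a in ang:
                rows.append((ecc * np.cos(a), ecc * np.sin(a), ecc))
        return np.asarray(rows)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters planted into a synthetic session.

    ``chain`` is the 8x8 embedded Markov chain of the semi-Markov state
    process (rows sum to 1, zero diagonal); holding times are gamma with
    shape 2 and mean ``dwell_mean``.  ``snr`` is the ratio of the per-channel
    RMS signal amplitude at the envelope peak to the noise SD.
    ``coupling_beta`` (dva per within-subject z-unit of planted D+ -> D-
    transition count) couples saccade-error spread to ground-truth dynamics;
    ``far_tp_boost`` perturbs the A- -> D- entry of the chain on far trials.
    """

    prototypes: PrototypeSet
    chain: np.ndarray
    dwell_mean: float = 0.08
    snr: float = 8.0
    coupling_beta: float = 0.2
    error_sigma: tuple[float, float] = (0.6, 0.85)  # (near, far), dva
    blink_prob: float = 0.2
    far_tp_boost: float = 0.08

    def __post_init__(self) -> None:
        chain = np.asarray(self.chain, dtype=float)
        object.__setattr__(self, "chain", chain)
        validate_chain(chain)
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def chain_for_eccentricity(self, ecc: float, far: float) -> np.ndarray:
        if self.far_tp_boost == 0.0 or ecc != far:
            return self.chain
        return boost_transition(self.chain, "A-", "D-", self.far_tp_boost)


def validate_chain(chain: np.ndarray) -> None:
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or chain.shape[0] != chain.shape[1]:
        raise ValueError("chain must be square")
    if np.any(np.diag(chain) != 0):
        raise ValueError("chain diagonal must be zero")
    sums = chain.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
    if bad.size:
        raise ValueError(f"chain row {bad[0]} sums to {sums[bad[0]]:.6f}, not 1")
    if np.any(chain < 0):
        raise ValueError("chain entries must be nonnegative")


def boost_transition(chain: np.ndarray, src: str, dst: str, delta: float) -> np.ndarray:
    """Increase one transition probability by ``delta`` and renormalise the row."""
    i, j = STATES_8.index(src), STATES_8.index(dst)
    out = np.asarray(chain, dtype=float).copy()
    row = out[i].copy()
    row[j] = min(row[j] + delta, 1.0)
    others = np.arange(row.size) != j
    rest = row[others].sum()
    if rest > 0:
        row[others] *= (1.0 - row[j]) / rest
    out[i] = row
    out[i, i] = 0.0
    out[i] /= out[i].sum()
    return out


def uniform_chain(k: int = 8) -> np.ndarray:
    """Zero-diagonal uniform chain: every other state equally likely next."""
    chain = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(chain, 0.0)
    return chain


def default_ground_truth(**overrides) -> GroundTruth:
    """Ground truth at the package's default study conditions."""
    overrides.setdefault("prototypes", make_template_prototypes(MONTAGE_20))
    overrides.setdefault("chain", uniform_chain(8))
    return GroundTruth(**overrides)


# ---------------------------------------------------------------------------
# template topographies


def make_template_prototypes(channel_names=MONTAGE_20) -> PrototypeSet:
    """The four canonical template maps and their negations, as 8 prototypes.

    A: right-frontal(+) to left-occipital(-) diagonal gradient; B: the
    mirrored diagonal; C: frontal(+) to occipital(-) axis; D: frontocentral
    midline maximum.  Maps are zero-mean across channels (average-referenced
    by construction) and unit norm; the negation of each is its "-" twin.

    The four maps are additionally projected (alternating projections) onto
    the set of map quartets with *equal per-channel energy*: summed over the
    four classes, every channel carries the same squared amplitude.  With
    near-uniform class occupancy this makes the per-channel variance of a
    generated session flat, so session-wide per-channel z-scoring is a
    uniform rescale and leaves the planted topographies undistorted — the
    property that makes end-to-end prototype recovery measurable against
    these same templates.
    """
    xy = montage_xy(channel_names)
    x, y = xy[:, 0], xy[:, 1]

    def unit(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.linalg.norm(v)

    # D is a difference of Gaussians: midline frontal maximum with a weak
    # negative surround, which keeps it well separated from the C gradient.
    bump = np.exp(-(x**2 + (y - 0.4) ** 2) / (2 * 0.3**2))
    surround = np.exp(-(x**2 + (y - 0.4) ** 2) / (2 * 0.66**2))
    raw = np.stack(
        [
            unit(np.sqrt(0.75) * x + 0.5 * y),
            unit(-np.sqrt(0.75) * x + 0.5 * y),
            unit(y),
            unit(bump - 0.7 * surround),
        ]
    )
    target = np.sqrt(raw.shape[0] / raw.shape[1])
    m = raw.copy()
    for _ in range(200):
        m = m / np.linalg.norm(m, axis=0) * target
        m = m - m.mean(axis=1, keepdims=True)
        m = m / np.linalg.norm(m, axis=1, keepdims=True)
    base = dict(zip(STATES_4, m))
    maps = np.zeros((8, len(channel_names)))
    pairing = {}
    for c, cls in enumerate(STATES_4):
        maps[2 * c] = base[cls]
        maps[2 * c + 1] = -base[cls]
        pairing[cls] = (2 * c, 2 * c + 1)
    return PrototypeSet(
        maps=maps, channel_names=tuple(channel_names), labels=STATES_8, pairing=pairing
    )


# ---------------------------------------------------------------------------
# semi-Markov state sequence


def simulate_label_sequence(
    chain: np.ndarray,
    dwell_mean: float,
    total_dur: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> LabelSequence:
    """Sample a semi-Markov label sequence.

    Holding times are gamma(shape=2, mean=``dwell_mean``) seconds, rounded to
    at least one sample; successive states follow ``chain`` (zero diagonal,
    row stochastic).  The initial state is uniform over states.
    """
    chain = np.asarray(chain, dtype=float)
    validate_chain(chain)
    if dwell_mean < 2.0 / fs:
        raise ValueError("dwell_mean must be at least two samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(total_dur * fs))
    k = chain.shape[0]
    labels = np.empty(n, dtype=np.int64)
    state = int(rng.integers(k))
    pos = 0
    while pos < n:
        dwell = rng.gamma(shape=2.0, scale=dwell_mean / 2.0)
        length = max(1, int(round(dwell * fs)))
        labels[pos : pos + length] = state
        pos += length
        state = int(rng.choice(k, p=chain[state]))
    return LabelSequence(labels=labels, fs=fs, mode=MODE_8, states=STATES_8)


# ---------------------------------------------------------------------------
# EEG


def simulate_eeg(
    labels: LabelSequence,
    prototypes: PrototypeSet,
    snr: float,
    seed: int | np.random.Generator = 0,
    peak_amp: float = 1.0,
) -> np.ndarray:
    """Render a label sequence into a (C, n) EEG array.

    Each segment's samples are its prototype scaled by a raised half-sine
    amplitude envelope (floor 0.5 of the peak) that crests mid-segment — so
    GFP maxima fall inside segments — while keeping signal present at
    segment boundaries, as in continuous EEG.  White Gaussian noise is added
    per channel with SD = peak signal RMS / snr.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if labels.labels.max(initial=0) >= prototypes.n_maps:
        raise ValueError("label indexes a prototype that does not exist")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = labels.n_samples
    c = prototypes.maps.shape[1]
    amp = np.empty(n)
    for _, start, length in labels.segments:
        i = np.arange(length)
        amp[start : start + length] = 0.5 + 0.5 * np.sin(np.pi * (i + 0.5) / length)
    amp *= peak_amp
    signal = prototypes.maps[labels.labels].T * amp  # (C, n)
    rms = np.sqrt(np.mean(prototypes.maps[0] ** 2))  # unit-norm maps: 1/sqrt(C)
    noise_sd = peak_amp * rms / snr
    if np.isfinite(noise_sd) and noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=(c, n))
    return signal


# ---------------------------------------------------------------------------
# gaze


def simulate_gaze(
    dur_s: float,
    go_time_s: float,
    target_px: tuple[float, float],
    error_sigma: float,
    blink_prob: float,
    px_per_deg: float,
    seed: int | np.random.Generator = 0,
    fs: float = 1000.0,
    center_px: tuple[float, float] = (683.0, 384.0),
    tremor_sd_dva: float = 0.02,
    latency_range: tuple[float, float] = (0.15, 0.25),
    saccade_dur: float = 0.03,
    blink_dur: float = 0.15,
) -> pd.DataFrame:
    """One trial's gaze trace: fixation, a saccade to the target, tremor.

    The eye fixates screen center through fixation/visual/memory, launches a
    smooth ~30 ms saccade after the go cue (with 150-250 ms latency), and
    settles on the target plus an isotropic Gaussian landing offset of SD
    ``error_sigma`` dva.  With probability ``blink_prob`` a blink interval is
    flagged somewhere inside the trial.  Columns: time_ms, x_px, y_px, blink.
    """
    if error_sigma < 0:
        raise ValueError("error_sigma must be nonnegative")
    if not 0.0 <= blink_prob <= 1.0:
        raise ValueError("blink_prob must be a probability")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    landing = (
        np.asarray(target_px, dtype=float)
        + rng.normal(0.0, error_sigma * px_per_deg, size=2)
    )
    latency = rng.uniform(*latency_range)
    t_on = go_time_s + latency
    # smooth (cosine-ramp) saccade profile from center to landing
    phase = np.clip((t - t_on) / saccade_dur, 0.0, 1.0)
    s = 0.5 - 0.5 * np.cos(np.pi * phase)
    pos = np.asarray(center_px)[None, :] + s[:, None] * (
        landing - np.asarray(center_px)
    )
    pos = pos + rng.normal(0.0, tremor_sd_dva * px_per_deg, size=pos.shape)
    blink = np.zeros(n, dtype=np.int64)
    if rng.uniform() < blink_prob:
        b0 = int(rng.uniform(0.0, max(dur_s - blink_dur, 0.0)) * fs)
        blink[b0 : b0 + int(blink_dur * fs)] = 1
    return pd.DataFrame(
        {
            "time_ms": t * 1000.0,
            "x_px": pos[:, 0],
            "y_px": pos[:, 1],
            "blink": blink,
        }
    )


# ---------------------------------------------------------------------------
# whole sessions


@dataclass
class SubjectData:
    """Everything generated for one subject."""

    subject: int
    eeg: np.ndarray  # (C, n) at cfg.fs_eeg
    events: pd.DataFrame  # EVENT_COLUMNS
    gaze: pd.DataFrame  # concatenated trial traces, absolute time_ms
    planted_labels: list[LabelSequence]  # one per trial, trial-local samples
    planted_dpdm_counts: np.ndarray  # D+ -> D- transitions in memory window


@dataclass
class Session:
    cfg: TaskConfig
    truth: GroundTruth
    subjects: list[SubjectData]


def _memory_transition_count(
    seq: LabelSequence, mem_start_s: float, mem_dur: float, src: str, dst: str
) -> int:
    """Planted src->dst segment transitions inside [mem_start, mem_start+dur)."""
    i = seq.states.index(src)
    j = seq.states.index(dst)
    lo = int(round(mem_start_s * seq.fs))
    hi = int(round((mem_start_s + mem_dur) * seq.fs))
    lab = seq.labels[lo:hi]
    segs = run_lengths(lab)
    count = 0
    for (a, _, _), (b, _, _) in zip(segs, segs[1:]):
        if a == i and b == j:
            count += 1
    return count


def simulate_session(
    cfg: TaskConfig, truth: GroundTruth, render_eeg: bool = True
) -> Session:
    """Generate a full multi-subject synthetic study.

    Per subject: a balanced, shuffled target schedule (each of the 12
    positions exactly n_trials/12 times), memory durations uniform in
    ``mem_dur_range`` (quantised to the EEG sample grid), per-trial planted
    label sequences rendered to EEG and concatenated back-to-back, and gaze
    whose per-trial landing spread is ``error_sigma`` for its eccentricity
    plus ``coupling_beta`` times the within-subject z-score of the planted
    D+ -> D- count in the memory window.

    ``render_eeg=False`` skips rendering the EEG arrays (events, gaze and
    planted sequences are unchanged — each trial draws from its own spawned
    random stream), which is handy for behavior-only experiments.
    """
    root = np.random.default_rng(cfg.seed)
    seeds = root.spawn(cfg.n_subjects)
    grid = cfg.target_grid_deg()
    far = max(cfg.eccentricities)
    subjects = []
    for s, srng in enumerate(seeds):
        reps = cfg.n_trials // cfg.n_positions
        order = np.repeat(np.arange(cfg.n_positions), reps)
        srng.shuffle(order)
        mem_durs = srng.uniform(*cfg.mem_dur_range, size=cfg.n_trials)
        mem_durs = np.round(mem_durs * cfg.fs_eeg) / cfg.fs_eeg
        trial_rngs = [r.spawn(3) for r in srng.spawn(cfg.n_trials)]
        # per-trial planted sequences and EEG
        planted, eeg_parts, rows = [], [], []
        t_cursor_samples = 0
        for tr in range(cfg.n_trials):
            pos = int(order[tr])
            ecc = grid[pos, 2]
            dur = cfg.fix_dur + cfg.stim_dur + mem_durs[tr] + cfg.sacc_dur
            chain = truth.chain_for_eccentricity(ecc, far)
            seq = simulate_label_sequence(
                chain, truth.dwell_mean, dur, cfg.fs_eeg, seed=trial_rngs[tr][0]
            )
            planted.append(seq)
            if render_eeg:
                eeg_parts.append(
                    simulate_eeg(seq, truth.prototypes, truth.snr, seed=trial_rngs[tr][1])
                )
            t0 = t_cursor_samples / cfg.fs_eeg
            rows.append(
                {
                    "subject": s,
                    "trial": tr,
                    "t_fix_on_s": t0,
                    "t_stim_on_s": t0 + cfg.fix_dur,
                    "t_stim_off_s": t0 + cfg.fix_dur + cfg.stim_dur,
                    "t_go_s": t0 + cfg.fix_dur + cfg.stim_dur + mem_durs[tr],
                    "target_index": pos,
                    "target_x_deg": grid[pos, 0],
                    "target_y_deg": grid[pos, 1],
                    "eccentricity_deg": ecc,
                }
            )
            t_cursor_samples += seq.n_samples
        events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
        if render_eeg:
            eeg = np.concatenate(eeg_parts, axis=1)
        else:
            eeg = np.zeros((truth.prototypes.maps.shape[1], 0))
        # planted D+ -> D- counts in the analysed memory window (first 1.5 s)
        counts = np.array(
            [
                _memory_transition_count(
                    planted[tr],
                    cfg.fix_dur + cfg.stim_dur,
                    min(1.5, mem_durs[tr]),
                    "D+",
                    "D-",
                )
                for tr in range(cfg.n_trials)
            ],
            dtype=float,
        )
        z = counts - counts.mean()
        z = z / counts.std() if counts.std() > 0 else np.zeros_like(z)
        # gaze, trial by trial, coupled through the planted dynamics
        near_sigma, far_sigma = truth.error_sigma
        gaze_parts = []
        for tr in range(cfg.n_trials):
            ecc = grid[int(order[tr]), 2]
            base = far_sigma if ecc == far else near_sigma
            sigma = max(0.05, base + truth.coupling_beta * z[tr])
            target_px = (
                cfg.center_px[0] + grid[int(order[tr]), 0] * cfg.px_per_deg,
                cfg.center_px[1] + grid[int(order[tr]), 1] * cfg.px_per_deg,
            )
            dur = planted[tr].n_samples / cfg.fs_eeg
            go_local = (
                events.loc[tr, "t_go_s"] - events.loc[tr, "t_fix_on_s"]
            )
            g = simulate_gaze(
                dur,
                float(go_local),
                target_px,
                sigma,
                truth.blink_prob,
                cfg.px_per_deg,
                seed=trial_rngs[tr][2],
                fs=cfg.fs_gaze,
                center_px=cfg.center_px,
            )
            g["time_ms"] = g["time_ms"] + events.loc[tr, "t_fix_on_s"] * 1000.0
            g.insert(0, "trial", tr)
            gaze_parts.append(g)
        gaze = pd.concat(gaze_parts, ignore_index=True)
        subjects.append(
            SubjectData(
                subject=s,
                eeg=eeg,
                events=events,
                gaze=gaze,
                planted_labels=planted,
                planted_dpdm_counts=counts,
            )
        )
    return Session(cfg=cfg, truth=truth, subjects=subjects)
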