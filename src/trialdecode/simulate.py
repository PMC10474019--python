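"""Synthetic multi-subject epoched EEG with known ground truth.

The generator emulates the structure of a single-trial ERP decoding study:
each subject sees the same set of image stimuli once, answers yes/no
(individual choice), and each stimulus additionally carries a market-level
outcome (funded / unfunded) that is constant across subjects.  The voltage
tensor for one subject is

    data[trial, ch, t] = erp(t) * topo[ch]
                       + sum_p 1[t in window_p] * amp_p * gain_subj
                                * (label_p(trial) - 1/2) * spatial_p[ch]
                       + spatially correlated Gaussian noise

so the grand-average evoked response is label-independent (classes are coded
+-1/2 around it) and all decodable signal lives in the configured pattern
windows.  Noise is white in time with a configurable channel covariance,
which makes the distinction between decoder weights and forward (Haufe)
patterns non-trivial downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: anterior-to-posterior 10-20 electrode families
CHANNEL_GROUPS = (
    "prefrontal",
    "frontal",
    "central",
    "temporal",
    "parietal",
    "occipital",
)


@dataclass(frozen=True)
class PatternSpec:
    """A class-conditional spatiotemporal pattern confined to a latency window.

    ``spatial`` is the ground-truth forward pattern (unit L2 norm over
    channels), ``window`` the (t0, t1) latency interval in seconds (closed at
    both ends on the sampling grid), ``amplitude`` the peak strength in uV and
    ``target`` which label modulates the pattern (``"choice"`` or
    ``"market"``).
    """

    spatial: np.ndarray
    window: tuple[float, float]
    amplitude: float
    target: str = "choice"

    def __post_init__(self):
        spatial = np.asarray(self.spatial, dtype=float)
        norm = np.linalg.norm(spatial)
        if norm == 0:
            raise ValueError("pattern spatial vector must be nonzero")
        object.__setattr__(self, "spatial", spatial / norm)
        t0, t1 = self.window
        if not t0 < t1:
            raise ValueError(f"pattern window must have t0 < t1, got {self.window}")
        if self.target not in ("choice", "market"):
            raise ValueError(f"pattern target must be 'choice' or 'market', got {self.target!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults are the desk-scale study: 8 subjects x 60 stimuli x 32 channels
    at 50 Hz over [-0.2, 0.8] s (51 samples).  ``full_scale_config`` gives the
    acquisition-matched 16 x 91 x 128 @ 100 Hz layout.
    """

    n_subjects: int = 8
    n_stimuli: int = 60
    n_channels: int = 32
    sfreq: float = 50.0
    t_start: float = -0.2
    t_end: float = 0.8
    erp_waveform: np.ndarray | None = None  # defaults to a canonical visual ERP
    patterns: tuple[PatternSpec, ...] = ()
    noise_cov: np.ndarray | None = None  # spatial correlation structure; default exponential
    noise_scale: float = 10.0  # per-channel noise sd, uV
    subject_effect_sd: float = 0.25  # lognormal sd of per-subject pattern gain
    p_funded: float = 43.0 / 91.0
    market_exact_count: bool = True  # exactly round(n * p_funded) funded stimuli
    p_choice: float = 0.5
    rho_choice_market: float = 0.0
    drop_fraction: float = 0.0  # fraction of trials dropped per subject (artifact analogue)
    seed: int = 0

    def __post_init__(self):
        if not (self.t_start < 0 < self.t_end):
            raise ValueError("epoch must contain stimulus onset: t_start < 0 < t_end")
        if not 0 <= self.p_funded <= 1:
            raise ValueError("p_funded must be in [0, 1]")
        if not 0 <= self.p_choice <= 1:
            raise ValueError("p_choice must be in [0, 1]")
        if not -1 <= self.rho_choice_market <= 1:
            raise ValueError("rho_choice_market must be in [-1, 1]")
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in [0, 1)")
        if self.noise_cov is not None:
            cov = np.asarray(self.noise_cov, dtype=float)
            if cov.shape != (self.n_channels, self.n_channels):
                raise ValueError(
                    f"noise_cov must be {self.n_channels} x {self.n_channels}, got {cov.shape}"
                )
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("noise_cov must be symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-10 * max(1.0, w.max()):
                raise ValueError(
                    f"noise_cov must be positive semi-definite (min eigenvalue {w.min():.3g})"
                )
            object.__setattr__(self, "noise_cov", cov)
        times = self.times
        for p in self.patterns:
            if len(p.spatial) != self.n_channels:
                raise ValueError(
                    f"pattern spatial length {len(p.spatial)} != n_channels {self.n_channels}"
                )
            t0, t1 = p.window
            if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
                raise ValueError(
                    f"pattern window {p.window} lies outside the epoch "
                    f"[{times[0]:.3f}, {times[-1]:.3f}]"
                )
        if self.erp_waveform is not None:
            erp = np.asarray(self.erp_waveform, dtype=float)
            if erp.shape != times.shape:
                raise ValueError(
                    f"erp_waveform must have {len(times)} samples, got {erp.shape}"
                )
            object.__setattr__(self, "erp_waveform", erp)

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) * self.sfreq)) + 1
        return self.t_start + np.arange(n) / self.sfreq

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """One subject's epoched voltages plus channel/time metadata.

    ``data`` is trials x channels x timepoints in uV; ``times`` in seconds
    relative to stimulus onset, uniformly spaced at 1/sfreq; every channel is
    assigned exactly one anterior-to-posterior 10-20 group.
    """

    subject_id: str
    data: np.ndarray
    ch_names: list[str]
    ch_groups: dict[str, str]
    times: np.ndarray
    sfreq: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_trials, n_ch, n_t = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError("ch_names length must match channel axis")
        if len(self.times) != n_t:
            raise ValueError("times length must match time axis")
        dt = np.diff(self.times)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6)):
            raise ValueError("times must be strictly increasing at 1/sfreq spacing")
        missing = [c for c in self.ch_names if c not in self.ch_groups]
        if missing:
            raise ValueError(f"channels without a group assignment: {missing[:5]}")
        bad = {g for g in self.ch_groups.values()} - set(CHANNEL_GROUPS)
        if bad:
            raise ValueError(f"unknown channel groups: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return EpochSet(
            subject_id=self.subject_id,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_groups=dict(self.ch_groups),
            times=self.times.copy(),
            sfreq=self.sfreq,
        )

    def group_channel_indices(self) -> dict[str, np.ndarray]:
        """Channel indices of each 10-20 group, in group order."""
        out = {}
        for g in CHANNEL_GROUPS:
            idx = [i for i, c in enumerate(self.ch_names) if self.ch_groups[c] == g]
            if idx:
                out[g] = np.asarray(idx)
        return out


TRIAL_TABLE_COLUMNS = ["subject_id", "stimulus_id", "trial_index", "choice", "market"]


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check the per-trial label table invariants.

    Market labels must be constant per stimulus across subjects (the market
    outcome is a property of the stimulus, not of the viewer).
    """
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    per_stim = trials.groupby("stimulus_id")["market"].nunique()
    if (per_stim > 1).any():
        bad = per_stim[per_stim > 1].index.tolist()
        raise ValueError(f"market label varies within stimulus: {bad[:5]}")


def default_erp_waveform(times: np.ndarray) -> np.ndarray:
    """A canonical visual evoked response: N1 dip, P2 peak, late positivity.

    Zero before stimulus onset; peak magnitude ~8 uV, in the range of a
    robust visual ERP.
    """
    times = np.asarray(times, dtype=float)

    def bump(center, width, amp):
        return amp * np.exp(-0.5 * ((times - center) / width) ** 2)

    erp = bump(0.11, 0.03, -6.0) + bump(0.22, 0.05, 8.0) + bump(0.45, 0.12, 4.0)
    erp[times < 0] = 0.0
    return erp


def default_base_topography(n_channels: int) -> np.ndarray:
    """Smooth posterior-weighted unit-norm topography for the evoked response."""
    x = np.linspace(0, np.pi, n_channels)
    topo = 0.4 + np.sin(x / 2) ** 2
    return topo / np.linalg.norm(topo)


def exponential_noise_cov(n_channels: int, length_scale: float = 5.0) -> np.ndarray:
    """Spatial correlation with exponential falloff in channel-index distance."""
    idx = np.arange(n_channels)
    return np.exp(-np.abs(idx[:, None] - idx[None, :]) / length_scale)


def default_channel_groups(ch_names: list[str]) -> dict[str, str]:
    """Assign channels to the six 10-20 families in contiguous blocks.

    The synthetic montage orders channels anterior to posterior, so equal
    blocks stand in for the net's real geometry.
    """
    n = len(ch_names)
    bounds = np.linspace(0, n, len(CHANNEL_GROUPS) + 1).astype(int)
    groups = {}
    for gi, g in enumerate(CHANNEL_GROUPS):
        for i in range(bounds[gi], bounds[gi + 1]):
            groups[ch_names[i]] = g
    return groups


def make_market_labels(
    n_stimuli: int,
    p_funded: float,
    seed: int,
    exact: bool = False,
) -> np.ndarray:
    """Per-stimulus binary funded/unfunded labels.

    With ``exact=True`` exactly ``round(n * p_funded)`` stimuli are funded
    (the study-count analogue, e.g. 43 of 91); otherwise labels are i.i.d.
    Bernoulli(p_funded).  Deterministic under ``seed``.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if not 0 <= p_funded <= 1:
        raise ValueError("p_funded must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if exact:
        n_ones = int(round(n_stimuli * p_funded))
        labels = np.zeros(n_stimuli, dtype=int)
        labels[rng.permutation(n_stimuli)[:n_ones]] = 1
        return labels
    return (rng.random(n_stimuli) < p_funded).astype(int)


def _choice_prob_given_market(market: np.ndarray, p_choice: float,
                              p_funded: float, rho: float) -> np.ndarray:
    """P(choice=1 | market) such that corr(choice, market) = rho exactly.

    cov(choice, market) = rho * sqrt(p_c (1-p_c) p_m (1-p_m)) is achieved by
    shifting the conditional Bernoulli rate linearly in (market - p_m).
    """
    if rho == 0 or p_funded in (0.0, 1.0) or p_choice in (0.0, 1.0):
        return np.full(market.shape, p_choice, dtype=float)
    slope = rho * np.sqrt(p_choice * (1 - p_choice) / (p_funded * (1 - p_funded)))
    prob = p_choice + slope * (market - p_funded)
    if prob.min() < -1e-12 or prob.max() > 1 + 1e-12:
        raise ValueError(
            f"rho_choice_market={rho} is infeasible for p_choice={p_choice}, "
            f"p_funded={p_funded}: conditional probability leaves [0, 1]"
        )
    return np.clip(prob, 0.0, 1.0)


def simulate_dataset(config: SimConfig) -> tuple[list[EpochSet], pd.DataFrame]:
    """Generate the full multi-subject dataset plus its trial table.

    Returns one :class:`EpochSet` per subject and a tidy table with one row
    per retained epoch (columns ``subject_id, stimulus_id, trial_index,
    choice, market``) aligned to epoch order.  Identical config (including
    seed) gives bit-identical output.
    """
    times = config.times
    n_t = len(times)
    erp = (np.asarray(config.erp_waveform, dtype=float)
           if config.erp_waveform is not None else default_erp_waveform(times))
    topo = default_base_topography(config.n_channels)
    cov = (config.noise_cov if config.noise_cov is not None
           else exponential_noise_cov(config.n_channels))
    # PSD was validated in SimConfig; jitter keeps Cholesky stable at the boundary
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(config.n_channels))
    background = np.outer(topo, erp)  # channels x timepoints

    ss = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    market = make_market_labels(
        config.n_stimuli, config.p_funded,
        seed=int(label_rng.integers(2**31)), exact=config.market_exact_count,
    )
    choice_prob = _choice_prob_given_market(
        market, config.p_choice, config.p_funded, config.rho_choice_market
    )

    stim_ids = [f"stim{i:03d}" for i in range(config.n_stimuli)]
    ch_names = [f"E{i + 1}" for i in range(config.n_channels)]
    ch_groups = default_channel_groups(ch_names)

    window_masks = [
        (times >= p.window[0] - 1e-12) & (times <= p.window[1] + 1e-12)
        for p in config.patterns
    ]

    epoch_sets: list[EpochSet] = []
    rows = []
    subject_seeds = ss.spawn(config.n_subjects)
    for s in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        subject_id = f"sub-{s + 1:02d}"
        gain = float(np.exp(config.subject_effect_sd * rng.standard_normal()))
        choice = (rng.random(config.n_stimuli) < choice_prob).astype(int)
        order = rng.permutation(config.n_stimuli)
        if config.drop_fraction > 0:
            n_keep = max(1, int(round(config.n_stimuli * (1 - config.drop_fraction))))
            order = order[:n_keep]
        n_trials = len(order)

        data = np.empty((n_trials, config.n_channels, n_t))
        noise = config.noise_scale * np.einsum(
            "cd,ndt->nct", chol, rng.standard_normal((n_trials, config.n_channels, n_t))
        )
        for ti, stim in enumerate(order):
            trial = background.copy()
            for p, mask in zip(config.patterns, window_masks):
                label = choice[stim] if p.target == "choice" else market[stim]
                trial[:, mask] += p.amplitude * gain * (label - 0.5) * p.spatial[:, None]
            data[ti] = trial + noise[ti]
            rows.append((subject_id, stim_ids[stim], ti, int(choice[stim]), int(market[stim])))

        epoch_sets.append(EpochSet(
            subject_id=subject_id, data=data, ch_names=ch_names,
            ch_groups=ch_groups, times=times.copy(), sfreq=config.sfreq,
        ))

    trials = pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
    validate_trial_table(trials)
    return epoch_sets, trials


def demo_pattern(n_channels: int, group_center: float = 0.8,
                 width: float = 0.15) -> np.ndarray:
    """A smooth unit-norm spatial pattern peaking at a relative scalp position."""
    x = np.linspace(0, 1, n_channels)
    spatial = np.exp(-0.5 * ((x - group_center) / width) ** 2)
    return spatial / np.linalg.norm(spatial)


def demo_config(seed: int = 0, amplitude: float = 10.0,
                rho_choice_market: float = 0.0) -> SimConfig:
    """Desk-scale config with a choice pattern at 200-300 ms and a weaker,
    earlier market pattern — the study layout in miniature."""
    n_ch = 32
    return SimConfig(
        patterns=(
            PatternSpec(demo_pattern(n_ch, 0.8), (0.2, 0.3), amplitude, "choice"),
            PatternSpec(demo_pattern(n_ch, 0.3), (0.2, 0.26), amplitude, "market"),
        ),
        rho_choice_market=rho_choice_market,
        seed=seed,
    )


def null_config(seed: int = 0) -> SimConfig:
    """Desk-scale config with no decodable signal (all pattern amplitudes 0)."""
    return SimConfig(seed=seed)


def full_scale_config(seed: int = 0, **kw) -> SimConfig:
    """Acquisition-matched layout: 16 subjects x 91 stimuli x 128 channels @ 100 Hz."""
    return SimConfig(n_subjects=16, n_stimuli=91, n_channels=128, sfreq=100.0,
                     seed=seed, **kw)
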