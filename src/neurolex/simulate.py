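"""Synthetic epoched EEG and behaviour for a three-session lexical-decision study.

Each simulated trial is 1/f^slope background noise (frequency-domain
synthesis, random phases, one independent stream per participant) plus
Gaussian-windowed half-sine ERP components planted on fixed electrode
groups with session-dependent amplitudes.  The spectral slope is also
session-dependent: a steeper slope means a more regular (more predictable)
signal and therefore lower fine-scale sample entropy, which is the lever
used to plant multiscale-entropy effects.

Behaviour (response time, accuracy, lexicality) is drawn from a
shifted-lognormal RT model with participant-level heterogeneity,
calibrated to the published condition means/SDs of the lexical-decision
task (word RTs ~811/764/727 ms across sessions; nonword ~925/825/779 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .montage import ACTICAP_64, COMPONENT_CHANNELS, validate_channels

__all__ = [
    "ErpComponentSpec",
    "RtModelSpec",
    "SimulationConfig",
    "default_components",
    "default_rt_model",
    "generate_behaviour",
    "generate_epochs",
    "simulate_participant",
]

SESSIONS = (1, 2, 3)
LEXICALITIES = ("word", "nonword")

# Published condition-level calibration targets: mean RT (ms),
# between-participant SD of participant means (ms), accuracy (proportion).
RT_MEANS_MS = {
    ("word", 1): 811.16, ("word", 2): 763.96, ("word", 3): 727.24,
    ("nonword", 1): 924.97, ("nonword", 2): 824.87, ("nonword", 3): 778.75,
}
RT_BETWEEN_SD_MS = {
    ("word", 1): 123.41, ("word", 2): 120.24, ("word", 3): 103.49,
    ("nonword", 1): 185.92, ("nonword", 2): 136.99, ("nonword", 3): 115.08,
}
ACCURACY = {
    ("word", 1): 0.87, ("word", 2): 0.86, ("word", 3): 0.86,
    ("nonword", 1): 0.92, ("nonword", 2): 0.94, ("nonword", 3): 0.93,
}


@dataclass(frozen=True)
class ErpComponentSpec:
    """One planted ERP component.

    Parameters
    ----------
    name : component label (N170, P200, N400, LPC or custom).
    channels : electrode labels carrying the component.
    peak_latency_ms : latency of the peak relative to stimulus onset.
    width_ms : full support of the half-sine (component is zero outside
        peak ± width/2).
    amplitude_by_session : signed peak amplitude in µV, one per session.
    polarity : extra sign flip (+1/-1); amplitudes may also carry the sign.
    """

    name: str
    channels: tuple[str, ...]
    peak_latency_ms: float
    width_ms: float
    amplitude_by_session: tuple[float, ...]
    polarity: int = 1

    def waveform(self, times_ms: np.ndarray, session_index: int) -> np.ndarray:
        """Gaussian-windowed half-sine, peak amplitude at peak_latency_ms."""
        amp = self.polarity * self.amplitude_by_session[session_index]
        t = np.asarray(times_ms, dtype=float)
        half = self.width_ms / 2.0
        phase = (t - self.peak_latency_ms + half) / self.width_ms
        support = (phase >= 0.0) & (phase <= 1.0)
        sine = np.where(support, np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
        gauss = np.exp(-0.5 * ((t - self.peak_latency_ms) / (self.width_ms / 4.0)) ** 2)
        return amp * sine * gauss


@dataclass(frozen=True)
class RtModelSpec:
    """Shifted-lognormal RT model with participant heterogeneity.

    For participant p in cell (lexicality, session) with target mean mu_c
    and between-participant SD sd_c, the participant's cell mean is
    ``mu_c + u_p * sd_c`` (u_p ~ N(0,1), shared across cells so
    fast participants are fast everywhere).  A trial RT is
    ``shift + Lognormal(m, sigma)`` with m chosen so the trial mean equals
    the participant's cell mean.  ``sigma`` is the trial-level lognormal
    shape; ``sigma=0`` gives degenerate (constant-per-cell) RTs.
    """

    mean_ms: dict = field(default_factory=lambda: dict(RT_MEANS_MS))
    between_sd_ms: dict = field(default_factory=lambda: dict(RT_BETWEEN_SD_MS))
    accuracy_prob: dict = field(default_factory=lambda: dict(ACCURACY))
    shift_ms: float = 200.0
    sigma: float = 0.35

    def validate(self, n_sessions: int) -> None:
        for lex in LEXICALITIES:
            for s in range(1, n_sessions + 1):
                key = (lex, s)
                for d, nm in ((self.mean_ms, "mean_ms"),
                              (self.between_sd_ms, "between_sd_ms"),
                              (self.accuracy_prob, "accuracy_prob")):
                    if key not in d:
                        raise ValueError(f"RtModelSpec.{nm} missing cell {key}")
                    if not np.isfinite(d[key]):
                        raise ValueError(f"RtModelSpec.{nm}[{key}] is not finite")
                if not 0.0 <= self.accuracy_prob[key] <= 1.0:
                    raise ValueError(f"accuracy_prob[{key}] outside [0, 1]")
        if not (np.isfinite(self.shift_ms) and np.isfinite(self.sigma)):
            raise ValueError("shift_ms and sigma must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def draw_trials(self, rng: np.random.Generator, u_p: float,
                    lexicality: str, session: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (rt_ms, correct) arrays for n trials of one participant-cell."""
        key = (lexicality, session)
        cell_mean = self.mean_ms[key] + u_p * self.between_sd_ms[key]
        # keep the lognormal part strictly positive even for slow outlier draws
        body = max(cell_mean - self.shift_ms, 25.0)
        m = math.log(body) - 0.5 * self.sigma ** 2
        rt = self.shift_ms + np.exp(rng.normal(m, self.sigma, size=n) if self.sigma > 0
                                    else np.full(n, m))
        correct = (rng.random(n) < self.accuracy_prob[key]).astype(np.int8)
        return rt, correct


def default_components() -> tuple[ErpComponentSpec, ...]:
    """Planted components mirroring the reported session effects.

    N170 more negative after Session 1; P200 and N400 more positive;
    LPC less positive.  Amplitudes in µV are free generator parameters
    (per-electrode effect sizes are not published), chosen to be
    physiologically plausible against ~10 µV background noise.
    """
    return (
        ErpComponentSpec("N170", COMPONENT_CHANNELS["N170"], 180.0, 70.0, (-2.0, -4.0, -4.0)),
        ErpComponentSpec("P200", COMPONENT_CHANNELS["P200"], 200.0, 90.0, (2.0, 3.5, 3.5)),
        ErpComponentSpec("N400", COMPONENT_CHANNELS["N400"], 400.0, 180.0, (-3.0, -1.5, -1.5)),
        ErpComponentSpec("LPC", COMPONENT_CHANNELS["LPC"], 700.0, 420.0, (3.0, 1.8, 1.8)),
    )


def default_rt_model() -> RtModelSpec:
    return RtModelSpec()


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Defaults mirror the study conditions: 20 participants, 3 EEG sessions,
    ~1000 correct-trial target per session, 64 channels at 500 Hz, epochs
    -200..+1000 ms.  ``noise_slope`` is the spectral exponent of the 1/f
    background per session; sessions 2-3 default to a steeper slope (more
    regular signal) so that fine-scale entropy drops after Session 1, the
    planted analogue of the reported multiscale-entropy decrease.
    """

    n_participants: int = 20
    n_sessions: int = 3
    trials_per_session: int = 1000
    channels: tuple[str, ...] = ACTICAP_64
    sampling_rate: float = 500.0
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0)
    rng_seed: int = 0
    noise_slope: tuple[float, ...] = (1.0, 1.3, 1.3)
    noise_sd_uv: float = 10.0
    components: tuple[ErpComponentSpec, ...] = field(default_factory=default_components)
    rt_model: RtModelSpec = field(default_factory=default_rt_model)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        span = self.epoch_window_ms[1] - self.epoch_window_ms[0]
        return int(round(span / 1000.0 * self.sampling_rate))

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        return self.epoch_window_ms[0] + dt * np.arange(self.n_samples)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("counts must be positive")
        if len(self.noise_slope) != self.n_sessions:
            raise ValueError("noise_slope must have one value per session")
        validate_channels(self.channels)
        lo, hi = self.epoch_window_ms
        for comp in self.components:
            if len(comp.amplitude_by_session) != self.n_sessions:
                raise ValueError(
                    f"component {comp.name}: amplitude_by_session must have "
                    f"length n_sessions={self.n_sessions}")
            if not (0.0 < comp.peak_latency_ms <= hi):
                raise ValueError(
                    f"component {comp.name}: peak latency {comp.peak_latency_ms} ms "
                    f"outside the post-stimulus window (0, {hi}] ms")
            validate_channels(comp.channels, self.channels)
        self.rt_model.validate(self.n_sessions)


def _participant_streams(config: SimulationConfig, participant: int):
    """Two independent RNG streams per participant (behaviour, EEG noise).

    Derived from the master seed via SeedSequence spawn keys, so a single
    participant can be regenerated bit-identically without simulating the
    rest of the cohort.
    """
    ss = np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(participant,))
    behav_ss, eeg_ss = ss.spawn(2)
    return np.random.default_rng(behav_ss), np.random.default_rng(eeg_ss)


def synth_noise(rng: np.random.Generator, n_trials: int, n_channels: int,
                n_samples: int, slope: float, sd: float) -> np.ndarray:
    """1/f^slope noise via spectral synthesis with random phases.

    Amplitude spectrum proportional to f^(-slope/2) (zero DC), phases
    uniform, inverse real FFT, each trace rescaled to the target SD.
    slope=0 reduces to white noise.
    """
    n_freq = n_samples // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-slope / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, n_channels, n_freq))
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * sd


def _behaviour_rows(config: SimulationConfig, participant: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Trial rows for one participant, all sessions, chronological order."""
    u_p = rng.normal()
    frames = []
    for session in range(1, config.n_sessions + 1):
        n = config.trials_per_session
        lex = np.where(rng.random(n) < 0.5, "word", "nonword")
        rt = np.empty(n)
        correct = np.empty(n, dtype=np.int8)
        for lx in LEXICALITIES:
            mask = lex == lx
            rt[mask], correct[mask] = config.rt_model.draw_trials(
                rng, u_p, lx, session, int(mask.sum()))
        frames.append(pd.DataFrame({
            "participant": participant,
            "session": session,
            "trial": np.arange(1, n + 1),
            "lexicality": lex,
            "rt_ms": rt,
            "correct": correct,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_participant(config: SimulationConfig, participant: int
                         ) -> tuple[dict[int, EpochSet], pd.DataFrame]:
    """Generate all sessions of one participant.

    Returns a dict session -> EpochSet plus the participant's trial log.
    Deterministic given (config.rng_seed, participant).
    """
    config.validate()
    behav_rng, eeg_rng = _participant_streams(config, participant)
    log = _behaviour_rows(config, participant, behav_rng)
    times = config.times_ms
    epochs: dict[int, EpochSet] = {}
    for session in range(1, config.n_sessions + 1):
        meta = log[log.session == session].reset_index(drop=True)
        n = len(meta)
        data = synth_noise(eeg_rng, n, config.n_channels, config.n_samples,
                           config.noise_slope[session - 1], config.noise_sd_uv)
        for comp in config.components:
            idx = [config.channels.index(ch) for ch in comp.channels]
            wave = comp.waveform(times, session - 1)
            data[:, idx, :] += wave
        epochs[session] = EpochSet(
            data=data, times_ms=times.copy(),
            channel_labels=tuple(config.channels),
            trial_meta=meta, sampling_rate=config.sampling_rate)
    return epochs, log


def generate_epochs(config: SimulationConfig, participants=None
                    ) -> tuple[dict[tuple[int, int], EpochSet], pd.DataFrame]:
    """Generate epochs and trial logs for a set of participants.

    Returns ``({(participant, session): EpochSet}, trial_log)``.  With the
    full defaults this is large (20 x 3 x 1000 x 64 x 600 samples); pass an
    explicit participant subset or a reduced config for interactive use.
    """
    config.validate()
    if participants is None:
        participants = range(1, config.n_participants + 1)
    out: dict[tuple[int, int], EpochSet] = {}
    logs = []
    for p in participants:
        sess_epochs, log = simulate_participant(config, p)
        for s, ep in sess_epochs.items():
            out[(p, s)] = ep
        logs.append(log)
    return out, pd.concat(logs, ignore_index=True)


def generate_behaviour(config: SimulationConfig, participants=None) -> pd.DataFrame:
    """Behaviour-only generation; identical rows to generate_epochs' log.

    Uses the same per-participant behaviour stream as the EEG generator, so
    RT/accuracy draws agree bit-for-bit with a full simulation.
    """
    config.validate()
    if participants is None:
        participants = range(1, config.n_participants + 1)
    frames = []
    for p in participants:
        behav_rng, _ = _participant_streams(config, p)
        frames.append(_behaviour_rows(config, p, behav_rng))
    return pd.concat(frames, ignore_index=True)


RECOVERY_CHANNELS: tuple[str, ...] = (
    "P7", "P8", "PO7", "PO8", "O1", "O2",      # N170 sites
    "Fz", "F1", "F2", "FC1", "FC2",            # P200 sites
    "Cz", "C3", "C4", "Pz", "Oz",              # unplanted sites
)


def recovery_config(**overrides) -> SimulationConfig:
    """Strong-signal conditions for end-to-end effect-recovery checks.

    A compact 16-electrode montage with a large planted Session-1-vs-(2,3)
    N170/P200 amplitude change and the steeper sessions-2-3 noise slope.
    The planted amplitudes are deliberately larger than the study-scale
    defaults: recovery validation runs at a small fraction of the study's
    subjects and trials, so the planted signal-to-noise is scaled up to
    keep the effect detectable at that size.  Defaults: 5 participants,
    100 trials/session.
    """
    base = SimulationConfig(
        n_participants=5,
        trials_per_session=100,
        channels=RECOVERY_CHANNELS,
        components=(
            ErpComponentSpec("N170", COMPONENT_CHANNELS["N170"], 180.0, 70.0,
                             (-2.0, -8.0, -8.0)),
            ErpComponentSpec("P200", COMPONENT_CHANNELS["P200"], 200.0, 90.0,
                             (2.0, 5.0, 5.0)),
        ),
    )
    return replace(base, **overrides)


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration: flat noise slope, session-constant components.

    Useful for calibration studies of the inference chain (permutation
    p-values should be uniform under this generator).
    """
    base = SimulationConfig()
    n_sessions = overrides.get("n_sessions", base.n_sessions)
    channels = overrides.get("channels", base.channels)
    comps = []
    for c in overrides.get("components", default_components()):
        chans = tuple(ch for ch in c.channels if ch in channels)
        if chans:
            comps.append(replace(
                c, channels=chans,
                amplitude_by_session=(c.amplitude_by_session[0],) * n_sessions))
    defaults = dict(noise_slope=(1.0,) * n_sessions, components=tuple(comps))
    defaults.update(overrides, components=tuple(comps))
    return replace(base, **defaults)
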