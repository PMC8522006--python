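"""Synthetic full-night ear-EEG: hypnograms, signals, events, imperfect scorers.

No public recording of around-the-ear sleep EEG with paired frontal
reference channels exists, so this module generates nights with the
statistical structure the analysis pipeline assumes:

* a first-order Markov hypnogram over {Art, W, N1, N2, N3, REM} in 30-s
  epochs, with dwell-time-dominated transitions typical of adult sleep;
* stage-conditioned source activity following AASM scoring conventions —
  10 Hz alpha in wake, 5 Hz theta in N1, sleep spindles (12–14 Hz,
  Hann-windowed, 0.5–2 s) and K-complexes (biphasic transients ≥ 0.5 s) on
  the N2 background, high-amplitude 1.5 Hz delta (≥ 75 µV at source) in N3,
  and low-amplitude mixed activity with opposite-polarity EOG deflections in
  REM;
* a single frontal source projected onto the eleven recorded channels
  (R1–R8, Fpz, EOG_L, EOG_R) through a fixed gain vector plus independent
  white sensor noise. The cEEGrid wraps around the ear, so the default gains
  form a C-shaped profile: the front-facing ends of the grid (R1 strongly,
  R8 mildly) see the frontal source with positive sign, the rear-facing
  middle electrodes (R4, R5) with negative sign. This reproduces the
  directional structure that correlation topography measures: front-pointing
  bipolar combinations correlate positively with Fpz, rear-pointing ones
  negatively;
* an imperfect second scorer that relabels epochs with a configurable error
  probability through an adjacent-stage-biased confusion kernel, emulating
  inter-rater disagreement.

Every generator is reproducible from (parameters, integer seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    BUNDLED_CONFUSIONS,
    STAGES,
    EventAnnotation,
    Hypnogram,
    Recording,
    bundled_confusion,
    write_confusion_csv,
    write_events,
    write_hypnogram,
    write_recording,
)
from .montage import CEEGRID_LABELS

#: Channel order of a simulated recording.
CHANNELS: tuple[str, ...] = CEEGRID_LABELS + ("Fpz", "EOG_L", "EOG_R")

# Stage transition matrix over (Art, W, N1, N2, N3, REM), 30-s epochs.
# Diagonal dominance sets realistic bout lengths (N2 median bout ~3 min,
# N3/REM bouts longer); Art epochs are rare and transient.
DEFAULT_TRANSITION = np.array(
    [
        [0.10, 0.30, 0.20, 0.30, 0.05, 0.05],
        [0.01, 0.75, 0.20, 0.02, 0.005, 0.015],
        [0.01, 0.09, 0.55, 0.33, 0.00, 0.02],
        [0.01, 0.02, 0.04, 0.85, 0.05, 0.03],
        [0.005, 0.005, 0.01, 0.08, 0.88, 0.02],
        [0.01, 0.03, 0.05, 0.05, 0.00, 0.86],
    ]
)

# Per-stage source spectra: sinusoidal components (freq Hz, amplitude µV)
# plus a 1/f "pink" background (standard deviation µV). Amplitudes follow
# AASM scoring conventions (alpha ~20 µV, slow waves >= 75 µV at source).
DEFAULT_STAGE_SPECTRA: dict[str, dict] = {
    "Art": {"oscillations": [], "background": 120.0},
    "W": {"oscillations": [(10.0, 20.0)], "background": 10.0},
    "N1": {"oscillations": [(5.0, 20.0)], "background": 10.0},
    "N2": {"oscillations": [], "background": 15.0},
    "N3": {"oscillations": [(1.5, 80.0)], "background": 15.0},
    "REM": {"oscillations": [], "background": 10.0},
}

# Scorer confusion kernel (zero diagonal): where an epoch goes when
# mislabeled, biased toward stages adjacent in depth (W<->N1<->N2<->N3,
# REM confusable with W/N1/N2).
DEFAULT_SCORER_KERNEL = np.array(
    [
        [0.00, 0.50, 0.20, 0.20, 0.05, 0.05],
        [0.10, 0.00, 0.60, 0.10, 0.05, 0.15],
        [0.05, 0.30, 0.00, 0.45, 0.05, 0.15],
        [0.05, 0.05, 0.35, 0.00, 0.35, 0.20],
        [0.02, 0.03, 0.05, 0.85, 0.00, 0.05],
        [0.05, 0.25, 0.30, 0.35, 0.05, 0.00],
    ]
)


def _check_row_stochastic(m: np.ndarray, name: str) -> None:
    m = np.asarray(m, dtype=float)
    if m.shape != (6, 6):
        raise ValueError(f"{name} must be 6x6 over the stage alphabet")
    if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must be non-negative and sum to 1")


@dataclass
class SleepModelParams:
    """Everything that shapes a simulated night apart from channel mixing."""

    stage_transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    epoch_length: float = 30.0
    fs: float = 250.0
    stage_spectra: dict = field(default_factory=lambda: {
        k: {"oscillations": list(v["oscillations"]), "background": v["background"]}
        for k, v in DEFAULT_STAGE_SPECTRA.items()
    })
    spindle_rate: float = 2.0       # events per minute of N2
    kcomplex_rate: float = 1.0      # events per minute of N2
    spindle_amp: float = 40.0       # µV at source
    kcomplex_amp: float = 100.0     # µV at source
    spindle_freq: tuple[float, float] = (12.0, 14.0)
    spindle_duration: tuple[float, float] = (0.5, 2.0)
    kcomplex_duration: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self):
        _check_row_stochastic(self.stage_transition, "stage_transition")
        if self.fs <= 0 or self.epoch_length <= 0:
            raise ValueError("fs and epoch_length must be positive")
        fmax = max(
            [f for s in self.stage_spectra.values() for f, _ in s["oscillations"]]
            + [self.spindle_freq[1]]
        )
        if self.fs <= 2 * fmax:
            raise ValueError(f"fs {self.fs} too low for component at {fmax} Hz")
        if self.spindle_rate < 0 or self.kcomplex_rate < 0:
            raise ValueError("event rates must be non-negative")


@dataclass
class SourceMixing:
    """Projection of the frontal source onto the recorded channels.

    ``gain["Fpz"]`` is fixed at 1 by definition (the source is expressed in
    Fpz units); the C-shaped cEEGrid default makes both grid ends face the
    source positively and the rear middle negatively.
    """

    gain: dict[str, float] = field(default_factory=lambda: {
        "R1": 1.00, "R2": 0.60, "R3": 0.10, "R4": -0.45,
        "R5": -0.30, "R6": -0.10, "R7": 0.05, "R8": 0.30,
        "Fpz": 1.0, "EOG_L": 0.70, "EOG_R": 0.70,
    })
    sensor_noise_sd: float = 8.0    # µV, white, independent per channel

    def __post_init__(self):
        missing = set(CHANNELS) - set(self.gain)
        if missing:
            raise ValueError(f"mixing gains missing channels {sorted(missing)}")
        if self.gain["Fpz"] != 1.0:
            raise ValueError("gain of Fpz defines the source scale and must be 1")
        if not self.sensor_noise_sd > 0:
            raise ValueError("sensor noise sd must be positive")


@dataclass
class ScorerNoiseParams:
    """Per-epoch mislabeling model of an imperfect second scorer."""

    error_prob: float = 0.15
    confusion_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_SCORER_KERNEL.copy()
    )
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_prob <= 1:
            raise ValueError("error_prob must be in [0, 1]")
        _check_row_stochastic(self.confusion_kernel, "confusion_kernel")
        if np.any(np.diag(self.confusion_kernel) != 0):
            raise ValueError("confusion kernel diagonal must be zero")


def simulate_hypnogram(
    params: SleepModelParams, n_epochs: int, seed: int | None = None
) -> Hypnogram:
    """First-order Markov hypnogram started in W."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cum = np.cumsum(params.stage_transition, axis=1)
    state = STAGES.index("W")
    stages = []
    for _ in range(n_epochs):
        stages.append(STAGES[state])
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    return Hypnogram(stages, params.epoch_length)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, scaled to the requested sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _spindle(rng, fs, f_lo, f_hi, d_lo, d_hi, amp):
    dur = rng.uniform(d_lo, d_hi)
    f = rng.uniform(f_lo, f_hi)
    n = max(2, int(round(dur * fs)))
    t = np.arange(n) / fs
    w = np.hanning(n)
    return amp * w * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)), n / fs


def _k_complex(rng, fs, d_lo, d_hi, amp):
    # one Hann-windowed period of a slow sine: sharp negative then positive
    dur = rng.uniform(d_lo, d_hi)
    n = max(2, int(round(dur * fs)))
    t = np.arange(n) / (n - 1)
    return -amp * np.hanning(n) * np.sin(2 * np.pi * t), n / fs


def _find_slot(rng, epoch_len, dur, occupied, tries: int = 100):
    """Uniform onset within the epoch avoiding occupied intervals (rejection)."""
    if dur >= epoch_len:
        return None
    for _ in range(tries):
        onset = rng.uniform(0, epoch_len - dur)
        if all(onset + dur <= o or onset >= o + d for o, d in occupied):
            return onset
    return None


def simulate_recording(
    h: Hypnogram,
    params: SleepModelParams | None = None,
    mixing: SourceMixing | None = None,
    seed: int | None = None,
) -> tuple[Recording, list[EventAnnotation]]:
    """Render a hypnogram into an 11-channel recording plus true event annotations.

    Stage-conditioned source activity (plus spindles and K-complexes during
    N2) is projected through the mixing gains onto R1–R8, Fpz and the EOG
    channels; REM adds opposite-polarity eye-movement deflections on
    EOG_L/EOG_R only; independent white sensor noise is added everywhere.
    """
    params = params or SleepModelParams()
    mixing = mixing or SourceMixing()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    n_ep = int(round(params.epoch_length * params.fs))
    n_total = n_ep * len(h)
    source = np.empty(n_total)
    eog = np.zeros((2, n_total))
    events: list[EventAnnotation] = []

    t_ep = np.arange(n_ep) / params.fs
    for k, stage in enumerate(h.stages):
        spec = params.stage_spectra[stage]
        seg = _pink_noise(rng, n_ep, spec["background"])
        for f, amp in spec["oscillations"]:
            seg = seg + amp * np.sin(2 * np.pi * f * t_ep + rng.uniform(0, 2 * np.pi))

        if stage == "N2":
            minutes = params.epoch_length / 60.0
            occupied: list[tuple[float, float]] = []
            for label, rate, maker in (
                ("spindle", params.spindle_rate,
                 lambda: _spindle(rng, params.fs, *params.spindle_freq,
                                  *params.spindle_duration, params.spindle_amp)),
                ("k_complex", params.kcomplex_rate,
                 lambda: _k_complex(rng, params.fs, *params.kcomplex_duration,
                                    params.kcomplex_amp)),
            ):
                for _ in range(rng.poisson(rate * minutes)):
                    wave, dur = maker()
                    onset = _find_slot(rng, params.epoch_length, dur, occupied)
                    if onset is None:
                        continue
                    occupied.append((onset, dur))
                    i = int(round(onset * params.fs))
                    seg[i : i + len(wave)] += wave[: n_ep - i]
                    events.append(
                        EventAnnotation(
                            onset=k * params.epoch_length + onset,
                            duration=dur,
                            label=label,
                            channel="Fpz",
                        )
                    )

        if stage == "REM":
            for _ in range(rng.poisson(2.0)):
                dur = rng.uniform(0.5, 1.0)
                onset = rng.uniform(0, params.epoch_length - dur)
                n = int(round(dur * params.fs))
                i = k * n_ep + int(round(onset * params.fs))
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n) / max(n - 1, 1)))
                amp = rng.choice([-100.0, 100.0])
                defl = np.concatenate([amp * ramp, amp * ramp[::-1]])
                defl = defl[: n_total - i]
                eog[0, i : i + len(defl)] += defl
                eog[1, i : i + len(defl)] -= defl

        source[k * n_ep : (k + 1) * n_ep] = seg

    gains = np.array([mixing.gain[c] for c in CHANNELS])
    data = gains[:, None] * source[None, :]
    data[CHANNELS.index("EOG_L")] += eog[0]
    data[CHANNELS.index("EOG_R")] += eog[1]
    data += rng.normal(0.0, mixing.sensor_noise_sd, size=data.shape)

    rec = Recording(CHANNELS, data, params.fs)
    return rec, sorted(events, key=lambda e: e.onset)


def corrupt_hypnogram(
    h: Hypnogram, noise: ScorerNoiseParams, seed: int | None = None
) -> Hypnogram:
    """Relabel each epoch independently with probability ``error_prob``."""
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    stages = []
    for s in h.stages:
        if rng.random() < noise.error_prob:
            row = noise.confusion_kernel[STAGES.index(s)]
            stages.append(STAGES[int(np.searchsorted(np.cumsum(row), rng.random(), side="right"))])
        else:
            stages.append(s)
    return Hypnogram(stages, h.epoch_length)


def expected_corrupted_kappa(h: Hypnogram, noise: ScorerNoiseParams) -> float:
    """Closed-form expected multi-class kappa of (h, corrupt_hypnogram(h)).

    With per-epoch error probability ε and kernel K, observed agreement is
    p_o = 1 − ε (the kernel diagonal is zero), and the corrupted rating's
    marginal at stage s is m_s = (1−ε) f_s + ε Σ_t f_t K[t,s] where f is the
    empirical stage frequency of ``h``; hence p_e = Σ_s f_s m_s.
    """
    f = np.array([h.stages.count(s) for s in STAGES], dtype=float)
    f /= f.sum()
    eps = noise.error_prob
    m = (1 - eps) * f + eps * (f @ noise.confusion_kernel)
    po = 1 - eps
    pe = float(f @ m)
    return (po - pe) / (1 - pe)


def make_fixture_suite(outdir, seed: int, hours: float = 8.0) -> dict[str, Path]:
    """Write a self-consistent set of fixtures for an end-to-end run.

    Produces a full-night EDF recording (default 8 h, the order of magnitude
    of a home sleep recording), its hypnogram, the true grapho-element
    annotations, a corrupted second-scorer hypnogram, and copies of the three
    published confusion-matrix tables bundled with the package.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s1, s2, s3 = (int(s.generate_state(1)[0] % 2**31)
                  for s in np.random.SeedSequence(seed).spawn(3))
    params = SleepModelParams(seed=s1)
    n_epochs = int(round(hours * 3600 / params.epoch_length))
    h = simulate_hypnogram(params, n_epochs, seed=s1)
    rec, events = simulate_recording(h, params, seed=s2)
    h2 = corrupt_hypnogram(h, ScorerNoiseParams(), seed=s3)

    paths = {
        "recording": outdir / "recording.edf",
        "hypnogram": outdir / "hypnogram.csv",
        "events": outdir / "events.csv",
        "hypnogram_rater2": outdir / "hypnogram_rater2.csv",
    }
    write_recording(rec, paths["recording"], format="edf")
    write_hypnogram(h, paths["hypnogram"])
    write_events(events, paths["events"])
    write_hypnogram(h2, paths["hypnogram_rater2"])
    for name in BUNDLED_CONFUSIONS:
        p = outdir / f"confusion_{name}.csv"
        write_confusion_csv(bundled_confusion(name), p)
        paths[f"confusion_{name}"] = p
    return paths
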