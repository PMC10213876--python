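"""Synthetic 24-h Holter ECG cohorts with known QT-RR structure.

Every subject carries a ground-truth linear QT-RR relation
``QT = alpha * RR + beta`` (ms), so the individualized QT interval
QTi = alpha * 1000 + beta is known by construction and every downstream
stage (template averaging, tangent T-end detection, per-subject
regression, cohort ROC analysis) can be validated without access to
clinical recordings.

Group calibration presets encode the published Holter-cohort
distributions for healthy controls and congenital long-QT-syndrome
(LQTS) carriers, per sex and per genotype (LQT1/LQT2/LQT3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "NormalParams",
    "SubjectProfile",
    "CohortCell",
    "CohortSpec",
    "GroundTruth",
    "reference_cohort",
    "genotype_cohort",
    "CONTROL_QT_RR_SLOPE",
    "LQTS_QT_RR_SLOPE",
    "sample_subject",
    "sample_cohort",
    "generate_rr_series",
    "synthesize_beat",
    "generate_recording",
    "simulate_qt_rr_points",
]

GROUPS = ("control", "LQTS", "LQT1", "LQT2", "LQT3")
SEXES = ("male", "female")

# Beat geometry (ms relative to QRS onset). The terminal limb of the T
# wave is exactly linear so the tangent construction has a closed-form
# target: the limb reaches the isoelectric line precisely at QT.
_P_CENTER, _P_SD, _P_AMP = -110.0, 22.0, 0.12
_Q_CENTER, _Q_SD, _Q_AMP = 12.0, 4.0, -0.10
_R_CENTER, _R_SD, _R_AMP = 40.0, 7.0, 1.00
_S_CENTER, _S_SD, _S_AMP = 64.0, 5.0, -0.18
_PRE_ONSET_MS = 160.0  # rendered lead-in before QRS onset (covers P)
_POST_END_MS = 60.0  # rendered tail after T end
R_OFFSET_MS = _R_CENTER  # R peak sits this far after QRS onset


@dataclass(frozen=True)
class NormalParams:
    """Mean and SD of a normally distributed group parameter."""

    mean: float
    sd: float

    def draw(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mean, self.sd, size=size)


#: Published control / pooled-LQTS QT-RR slope distributions.
CONTROL_QT_RR_SLOPE = NormalParams(0.168, 0.045)
LQTS_QT_RR_SLOPE = NormalParams(0.216, 0.090)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one synthetic subject."""

    subject_id: str
    group: str  # control | LQTS | LQT1 | LQT2 | LQT3
    sex: str  # male | female
    alpha_true: float  # QT-RR slope (ms QT per ms RR), dimensionless
    beta_true: float  # QT-RR intercept, ms
    qt_noise_sd: float = 5.0  # beat-level QT scatter, ms
    rr_mean: float = 828.0  # ms
    rr_circadian_amp: float = 80.0  # ms, day/night sinusoid amplitude
    rr_short_term_sd: float = 30.0  # ms, AR(1) beat-to-beat jitter
    ectopy_rate: float = 0.002  # fraction of beats
    t_amplitude: float = 0.35  # mV; negative = inverted T
    noise_sd: float = 0.02  # mV additive white noise
    wander_amp: float = 0.05  # mV baseline wander amplitude

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (0.0 <= self.alpha_true < 1.0):
            raise ValueError("alpha_true must lie in [0, 1)")
        if self.beta_true <= 0.0:
            raise ValueError("beta_true must be positive")
        if not (400.0 <= self.rr_mean <= 1500.0):
            raise ValueError("rr_mean must lie in [400, 1500] ms")

    @property
    def qti_true(self) -> float:
        """Ground-truth QTi = alpha * 1000 + beta, ms."""
        return self.alpha_true * 1000.0 + self.beta_true

    @property
    def is_lqts(self) -> bool:
        return self.group != "control"


@dataclass(frozen=True)
class CohortCell:
    """Group parameters for one (group, sex) cell of a cohort design."""

    n: int
    qti: NormalParams  # QTi distribution, ms
    alpha: NormalParams  # QT-RR slope distribution
    rr: NormalParams  # mean RR distribution, ms
    qt_noise_sd: float = 5.0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("cell count must be >= 0")
        for p in (self.qti, self.alpha, self.rr):
            if p.sd < 0:
                raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A full cohort design: one :class:`CohortCell` per (group, sex)."""

    cells: dict = field(default_factory=dict)  # (group, sex) -> CohortCell
    name: str = "custom"

    def cell(self, group: str, sex: str) -> CohortCell:
        try:
            return self.cells[(group, sex)]
        except KeyError:
            raise KeyError(
                f"no cohort cell for group={group!r}, sex={sex!r}"
            ) from None


def reference_cohort() -> CohortSpec:
    """Sex-split calibration preset: controls vs pooled LQTS carriers.

    Encodes the published per-sex group sizes and the QTi, QT-RR slope
    and mean-RR distributions of the derivation cohort (controls
    n=102/99, LQTS n=115/139 for males/females).
    """
    cells = {
        ("control", "male"): CohortCell(
            102, NormalParams(390, 19), NormalParams(0.147, 0.031),
            NormalParams(845, 105)),
        ("control", "female"): CohortCell(
            99, NormalParams(409, 21), NormalParams(0.189, 0.048),
            NormalParams(810, 113)),
        ("LQTS", "male"): CohortCell(
            115, NormalParams(465, 36), NormalParams(0.212, 0.093),
            NormalParams(906, 146)),
        ("LQTS", "female"): CohortCell(
            139, NormalParams(475, 34), NormalParams(0.220, 0.088),
            NormalParams(864, 137)),
    }
    return CohortSpec(cells=cells, name="reference")


def genotype_cohort() -> CohortSpec:
    """Genotype-resolved preset (LQT1/LQT2/LQT3 vs controls).

    QTi and slope distributions per genotype follow the published
    subtype tables; LQT1 and LQT2 slope distributions are sex-specific
    where the source reports them separately.
    """
    cells = {
        ("control", "male"): CohortCell(
            102, NormalParams(390, 19), NormalParams(0.147, 0.031),
            NormalParams(845, 105)),
        ("control", "female"): CohortCell(
            99, NormalParams(409, 21), NormalParams(0.189, 0.048),
            NormalParams(810, 113)),
        ("LQT1", "male"): CohortCell(
            69, NormalParams(460, 31), NormalParams(0.162, 0.059),
            NormalParams(884, 135)),
        ("LQT1", "female"): CohortCell(
            94, NormalParams(460, 31), NormalParams(0.193, 0.079),
            NormalParams(884, 135)),
        ("LQT2", "male"): CohortCell(
            39, NormalParams(486, 35), NormalParams(0.279, 0.083),
            NormalParams(882, 161)),
        ("LQT2", "female"): CohortCell(
            39, NormalParams(486, 35), NormalParams(0.273, 0.083),
            NormalParams(882, 161)),
        ("LQT3", "male"): CohortCell(
            7, NormalParams(497, 44), NormalParams(0.315, 0.069),
            NormalParams(880, 116)),
        ("LQT3", "female"): CohortCell(
            6, NormalParams(497, 44), NormalParams(0.315, 0.069),
            NormalParams(880, 116)),
    }
    return CohortSpec(cells=cells, name="genotype")


def sample_subject(
    spec: CohortSpec,
    group: str,
    sex: str,
    rng: np.random.Generator,
    subject_id: str | None = None,
    **profile_overrides,
) -> SubjectProfile:
    """Draw one subject from the (group, sex) cell of a cohort design.

    alpha and QTi are drawn from the cell's normal distributions and the
    intercept derived as ``beta = QTi - 1000 * alpha`` (the published
    tables parameterize QTi, not beta). Draws are clipped to keep the
    profile physiological: alpha into [0.02, 0.6] and below the value
    that would drive beta non-positive, mean RR into [450, 1450] ms.
    """
    cell = spec.cell(group, sex)
    alpha = float(cell.alpha.draw(rng))
    qti = float(cell.qti.draw(rng))
    rr_mean = float(np.clip(cell.rr.draw(rng), 450.0, 1450.0))
    alpha = float(np.clip(alpha, 0.02, min(0.6, (qti - 10.0) / 1000.0)))
    beta = qti - 1000.0 * alpha
    if subject_id is None:
        subject_id = f"{group}-{sex}-{rng.integers(0, 10**8):08d}"
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        sex=sex,
        alpha_true=alpha,
        beta_true=beta,
        qt_noise_sd=cell.qt_noise_sd,
        rr_mean=rr_mean,
        **profile_overrides,
    )


def sample_cohort(
    spec: CohortSpec, rng: np.random.Generator, **profile_overrides
) -> list[SubjectProfile]:
    """Sample every cell of a cohort design; returns all profiles."""
    profiles = []
    for (group, sex), cell in spec.cells.items():
        for i in range(cell.n):
            profiles.append(
                sample_subject(
                    spec, group, sex, rng,
                    subject_id=f"{group}-{sex}-{i:04d}",
                    **profile_overrides,
                )
            )
    return profiles


def generate_rr_series(
    profile: SubjectProfile,
    duration_s: float,
    rng: np.random.Generator,
    night_center_s: float = 18 * 3600.0,
    ar_coeff: float = 0.9,
) -> np.ndarray:
    """RR interval sequence (ms) covering ``duration_s`` seconds.

    A single 24-h sinusoid modulates the mean (longest RR at
    ``night_center_s`` into the recording) and an AR(1) process with
    stationary SD ``rr_short_term_sd`` supplies beat-to-beat jitter.
    The sequence is truncated where cumulative time first exceeds the
    requested duration.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    lo = max(300.0, profile.rr_mean - profile.rr_circadian_amp
             - 4 * profile.rr_short_term_sd)
    n = int(duration_s * 1000.0 / lo) + 8
    eps = rng.normal(0.0, profile.rr_short_term_sd
                     * np.sqrt(1.0 - ar_coeff**2), size=n)
    eps[0] = rng.normal(0.0, profile.rr_short_term_sd)
    jitter = lfilter([1.0], [1.0, -ar_coeff], eps)
    # circadian term evaluated at the nominal beat times; the sinusoid
    # varies on hours, so the approximation error is negligible
    t_nominal = np.arange(n) * (profile.rr_mean / 1000.0)
    circ = profile.rr_circadian_amp * np.cos(
        2 * np.pi * (t_nominal - night_center_s) / 86400.0)
    rr = np.maximum(profile.rr_mean + circ + jitter, 300.0)
    cum = np.cumsum(rr) / 1000.0
    k = int(np.searchsorted(cum, duration_s, side="left"))
    return rr[: max(k, 1)]


def _gauss(t_ms, center, sd, amp):
    return amp * np.exp(-0.5 * ((t_ms - center) / sd) ** 2)


def _t_wave(t_ms: np.ndarray, qt_ms: float, amplitude: float) -> np.ndarray:
    """T wave with a half-cosine upslope and an exactly linear terminal
    limb that reaches baseline at ``qt_ms`` after QRS onset."""
    if amplitude == 0.0:
        return np.zeros_like(t_ms)
    t_on = max(90.0, 0.25 * qt_ms)
    if t_on >= qt_ms:  # degenerate short QT: no room for a T wave
        return np.zeros_like(t_ms)
    apex = t_on + 0.6 * (qt_ms - t_on)
    w = np.zeros_like(t_ms)
    rise = (t_ms >= t_on) & (t_ms < apex)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - t_on) / (apex - t_on)))
    fall = (t_ms >= apex) & (t_ms < qt_ms)
    w[fall] = (qt_ms - t_ms[fall]) / (qt_ms - apex)
    return amplitude * w


def synthesize_beat(
    qt_ms: float,
    rr_ms: float,
    profile: SubjectProfile,
    fs_hz: float,
    ectopic: bool = False,
) -> np.ndarray:
    """Render one beat (mV) sampled at ``fs_hz``.

    The returned waveform starts ``R_OFFSET_MS + 120`` ms before the R
    peak; QRS onset falls at sample ``round(160e-3 * fs_hz)``. The T
    wave's linear terminal limb crosses the isoelectric level (0 mV)
    exactly ``qt_ms`` after QRS onset, which is the recoverable target
    of the tangent method.
    """
    if fs_hz < 128:
        raise ValueError("fs_hz must be >= 128")
    if not (0.0 < qt_ms < rr_ms):
        raise ValueError("require 0 < qt_ms < rr_ms")
    n = int(round((_PRE_ONSET_MS + qt_ms + _POST_END_MS) * fs_hz / 1000.0))
    t_ms = np.arange(n) * (1000.0 / fs_hz) - _PRE_ONSET_MS
    if ectopic:
        # wide bizarre QRS, no P wave, discordant T
        w = _gauss(t_ms, 60.0, 24.0, 1.3 * np.sign(_R_AMP))
        w += _t_wave(t_ms, min(qt_ms, 0.85 * rr_ms), -0.6 * profile.t_amplitude)
        return w
    w = _gauss(t_ms, _P_CENTER, _P_SD, _P_AMP)
    w += _gauss(t_ms, _Q_CENTER, _Q_SD, _Q_AMP)
    w += _gauss(t_ms, _R_CENTER, _R_SD, _R_AMP)
    w += _gauss(t_ms, _S_CENTER, _S_SD, _S_AMP)
    w += _t_wave(t_ms, qt_ms, profile.t_amplitude)
    return w


@dataclass
class GroundTruth:
    """Per-beat oracle annotations for one synthetic recording."""

    beats: pd.DataFrame  # beat_index, r_peak_s, qrs_onset_s, t_end_s,
    #                      qt_ms, rr_ms, ectopic
    alpha_true: float
    beta_true: float

    def to_csv(self, path) -> None:
        self.beats.to_csv(path, index=False)


def generate_recording(
    profile: SubjectProfile,
    duration_s: float,
    fs_hz: float = 200.0,
    n_channels: int = 2,
    rng: np.random.Generator | None = None,
):
    """Synthesize a multichannel Holter recording plus its ground truth.

    Beats are laid down on the RR series from :func:`generate_rr_series`;
    each beat's QT is ``alpha_true * RR_prev + beta_true`` plus Gaussian
    noise of SD ``qt_noise_sd``, with RR_prev the sample-aligned
    preceding interval so noise-free ground-truth points lie exactly on
    the subject's line. Baseline wander (two slow sinusoids) and white
    noise are added per channel.

    Returns ``(ECGRecording, GroundTruth)``.
    """
    from .processing import ECGRecording  # local import avoids a cycle

    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_channels not in (2, 3):
        raise ValueError("n_channels must be 2 or 3")
    if rng is None:
        rng = np.random.default_rng()

    rr = generate_rr_series(profile, duration_s, rng)
    r_times = 0.4 + np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
    r_times = r_times[r_times < duration_s - 0.2]
    n_beats = len(r_times)
    n_samples = int(round(duration_s * fs_hz))
    r_samples = np.round(r_times * fs_hz).astype(np.int64)
    onset_off = int(round(R_OFFSET_MS * fs_hz / 1000.0))
    onset_samples = r_samples - onset_off

    # sample-aligned preceding RR, ms; first beat uses the subject mean
    rr_prev = np.empty(n_beats)
    rr_prev[0] = profile.rr_mean
    rr_prev[1:] = np.diff(r_samples) / fs_hz * 1000.0

    qt = (profile.alpha_true * rr_prev + profile.beta_true
          + rng.normal(0.0, profile.qt_noise_sd, size=n_beats))
    ectopic = rng.random(n_beats) < profile.ectopy_rate
    qt = np.minimum(qt, 0.92 * rr_prev)  # keep T inside the cycle

    base = np.zeros(n_samples, dtype=np.float64)
    pre = int(round(_PRE_ONSET_MS * fs_hz / 1000.0))
    for i in range(n_beats):
        w = synthesize_beat(qt[i], max(rr_prev[i], qt[i] + 1.0), profile,
                            fs_hz, ectopic=bool(ectopic[i]))
        s0 = onset_samples[i] - pre
        s1 = s0 + len(w)
        a = max(s0, 0)
        b = min(s1, n_samples)
        if a < b:
            base[a:b] += w[a - s0: b - s0]

    t = np.arange(n_samples) / fs_hz
    gains = (1.0, 0.6, 0.8)[:n_channels]
    signal = np.empty((n_channels, n_samples), dtype=np.float32)
    for c in range(n_channels):
        wander = (profile.wander_amp
                  * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
                  + 1.2 * profile.wander_amp
                  * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi)))
        noise = rng.normal(0.0, profile.noise_sd, size=n_samples)
        signal[c] = (gains[c] * base + wander + noise).astype(np.float32)

    qt_truth = qt.copy()
    qt_truth[ectopic] = np.nan  # ectopic beats carry no valid QT
    beats = pd.DataFrame(
        {
            "beat_index": np.arange(n_beats),
            "r_peak_s": r_samples / fs_hz,
            "qrs_onset_s": onset_samples / fs_hz,
            "t_end_s": onset_samples / fs_hz + qt_truth / 1000.0,
            "qt_ms": qt_truth,
            "rr_ms": rr_prev,
            "ectopic": ectopic,
        }
    )
    recording = ECGRecording(
        signal=signal,
        fs_hz=fs_hz,
        start_time="00:00:00",
        channel_labels=[f"ch{c + 1}" for c in range(n_channels)],
        subject_id=profile.subject_id,
    )
    truth = GroundTruth(beats=beats, alpha_true=profile.alpha_true,
                        beta_true=profile.beta_true)
    return recording, truth


def simulate_qt_rr_points(
    profile: SubjectProfile,
    n_windows: int = 2880,
    window_s: float = 30.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Template-level (QT, RR) scatter without waveform synthesis.

    Emulates what full measurement of a recording produces: one point
    per 30-s window, RR from the circadian + jitter model averaged over
    the window, QT on the subject's line with noise shrunk by the
    number of beats averaged per template. Useful for fast
    statistical-level simulation (repeat-recording stability, cohort
    calibration) where waveform rendering adds nothing.
    """
    if rng is None:
        rng = np.random.default_rng()
    t_centers = (np.arange(n_windows) + 0.5) * window_s
    circ = profile.rr_circadian_amp * np.cos(
        2 * np.pi * (t_centers - 18 * 3600.0) / 86400.0)
    m = np.maximum(window_s * 1000.0 / profile.rr_mean, 1.0)  # beats/window
    rr = (profile.rr_mean + circ
          + rng.normal(0.0, profile.rr_short_term_sd / np.sqrt(m),
                       size=n_windows))
    qt = (profile.alpha_true * rr + profile.beta_true
          + rng.normal(0.0, profile.qt_noise_sd / np.sqrt(m), size=n_windows))
    return pd.DataFrame(
        {"window_index": np.arange(n_windows), "rr_ms": rr, "qt_ms": qt}
    )
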