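"""Seedable synthetic resting-state EEG with known spectral ground truth.

The generator emulates a 5-minute, 19-channel, eyes-closed scalp recording
sampled at 250 Hz: a 1/f^beta aperiodic background plus narrow-band theta and
alpha oscillations.  Oscillations are band-filtered noise processes, not pure
tones, so spectral peaks have realistic width and anchor detection is a
genuine estimation problem.  Absolute units are nominal microvolts; everything
downstream works on relative power, so only ratios matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: Standard 19-electrode 10-20 montage used throughout.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


class ValidationError(ValueError):
    """A config or argument field failed validation; the message names it."""


@dataclass(frozen=True)
class EegSimConfig:
    """Ground-truth parameters of a simulated recording.

    Parameters
    ----------
    n_channels : number of scalp channels (19-name montage if 19).
    fs : sampling rate in Hz; must exceed 90 Hz so the 2-45 Hz analysis
        range is representable.
    duration : recording length in seconds.
    iaf_true : center frequency (Hz) of the alpha oscillation, the
        ground-truth individual alpha frequency.
    alpha_power : amplitude of the alpha process relative to the background
        noise scale (standard-deviation units).
    theta_freq, theta_power : same for the theta oscillation.
    aperiodic_exponent : beta of the 1/f^beta background, applied over
        0.3-70 Hz (the acquisition band-pass of the emulated amplifier).
    noise_scale : standard deviation of the background, nominal microvolts.
    artifact_rate : transient artifacts per minute injected on top.
    coherence : 0..1, fraction of each oscillation shared across channels;
        the study's true value is unknown, this is a free knob.
    """

    n_channels: int = 19
    fs: float = 250.0
    duration: float = 300.0
    iaf_true: float = 10.0
    alpha_power: float = 2.0
    theta_freq: float = 6.0
    theta_power: float = 0.8
    aperiodic_exponent: float = 1.0
    noise_scale: float = 1.0
    artifact_rate: float = 0.0
    coherence: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if not self.fs > 90.0:
            raise ValidationError("fs must exceed 90 Hz (2x the 45 Hz analysis edge)")
        n_samples = self.duration * self.fs
        if self.duration <= 0 or abs(n_samples - round(n_samples)) > 1e-9:
            raise ValidationError("duration x fs must be a positive integer sample count")
        if not 5.0 <= self.iaf_true <= 14.0:
            raise ValidationError("iaf_true must lie in [5, 14] Hz")
        for name in ("alpha_power", "theta_power", "noise_scale", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValidationError("coherence must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class Recording:
    """A multichannel signal matrix (channels x time) with metadata."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    reference: str = "linked-mastoid"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError("channel count does not match channel_labels")
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _shaped_background(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                       exponent: float, scale: float) -> np.ndarray:
    """White noise spectrally shaped to 1/f^exponent over 0.3-70 Hz.

    The amplitude factor f^(-exponent/2) is clamped outside the acquisition
    band so the DC bin and frequencies beyond the hardware band-pass are not
    amplified.
    """
    white = rng.standard_normal((n_ch, n))
    if exponent == 0.0:
        return scale * white
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.clip(f, 0.3, 70.0)
    shaping = f_eff ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * shaped / sd


def _narrowband(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                center: float, bandwidth: float, amplitude: float,
                coherence: float) -> np.ndarray:
    """Band-filtered noise oscillation of unit-calibrated amplitude.

    A shared source (weight sqrt(coherence)) plus independent per-channel
    sources give controllable inter-channel coherence; per-channel random
    gains of +/-20% make the channel average a genuine average.
    """
    if amplitude == 0.0:
        return np.zeros((n_ch, n))
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = center + bandwidth / 2.0
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(4 * fs)  # discard filter transients
    shared = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    own = signal.sosfilt(sos, rng.standard_normal((n_ch, n + pad)), axis=1)[:, pad:]
    mix = np.sqrt(coherence) * shared[None, :] + np.sqrt(1.0 - coherence) * own
    sd = mix.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    gains = 1.0 + rng.uniform(-0.2, 0.2, size=(n_ch, 1))
    return amplitude * gains * mix / sd


def generate_recording(config: EegSimConfig) -> Recording:
    """Simulate a resting recording whose collapsed spectrum peaks at
    ``iaf_true`` when the alpha oscillation dominates the background.

    Identical configs (the seed is part of the config) give bitwise-identical
    sample matrices.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    x = _shaped_background(rng, config.n_channels, n, config.fs,
                           config.aperiodic_exponent, config.noise_scale)
    x += _narrowband(rng, config.n_channels, n, config.fs, config.iaf_true,
                     1.5, config.alpha_power * config.noise_scale,
                     config.coherence)
    x += _narrowband(rng, config.n_channels, n, config.fs, config.theta_freq,
                     1.0, config.theta_power * config.noise_scale,
                     config.coherence)
    labels = MONTAGE_1020 if config.n_channels == 19 else tuple(
        f"CH{i + 1}" for i in range(config.n_channels))
    rec = Recording(samples=x, fs=config.fs, channel_labels=labels)
    if config.artifact_rate > 0:
        rec, _ = inject_artifacts(rec, rate=config.artifact_rate,
                                  amplitude=20.0 * config.noise_scale,
                                  seed=config.seed + 1)
    return rec


def inject_artifacts(rec: Recording, rate: float, amplitude: float,
                     seed: int, width_s: float = 0.2):
    """Superimpose high-amplitude transients (Poisson count, mean
    ``rate x minutes``) at random times; returns a copy and the event log.

    Each event is a half-sine pulse of the given nominal peak amplitude with
    a random per-channel gain in [0.5, 1.5] — a crude stand-in for
    ocular/movement artifacts.  The gains make the event survive
    common-average re-referencing (a perfectly common-mode transient would
    cancel), so epoch rejection can be tested against the injection log.
    """
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if rate == 0:
        return rec, []
    rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(rate * rec.duration / 60.0))
    width = max(int(round(width_s * rec.fs)), 1)
    pulse = amplitude * np.sin(np.pi * np.arange(width) / width)
    out = rec.samples.copy()
    events: list[int] = []
    for _ in range(n_events):
        start = int(rng.integers(0, max(rec.n_samples - width, 1)))
        gains = rng.uniform(0.5, 1.5, size=(rec.n_channels, 1))
        out[:, start:start + width] += gains * pulse[: rec.n_samples - start]
        events.append(start)
    new = Recording(samples=out, fs=rec.fs,
                    channel_labels=rec.channel_labels, reference=rec.reference)
    return new, sorted(events)


# ---------------------------------------------------------------------------
# I/O: CSV is the tested interchange dialect (rows = channels, one metadata
# line for fs); EDF output is not offered because no EDF writer library is a
# dependency — recordings can still be *read* from EDF, see spectra.read_recording.

def write_recording_csv(rec: Recording, path) -> None:
    """Write ``# fs=<Hz> reference=<ref>`` then a header of channel labels and
    one column per channel (samples in rows)."""
    header = "# fs=%g reference=%s\n" % (rec.fs, rec.reference)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.8g")


def read_recording_csv(path) -> Recording:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# fs="):
            raise ValidationError(f"{path}: missing '# fs=' metadata line")
        fields = dict(kv.split("=") for kv in meta[2:].split())
        labels = tuple(fh.readline().strip().split(","))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return Recording(samples=data.T, fs=float(fields["fs"]),
                     channel_labels=labels,
                     reference=fields.get("reference", "linked-mastoid"))


__all__ = [
    "MONTAGE_1020", "ValidationError", "EegSimConfig", "Recording",
    "generate_recording", "inject_artifacts",
    "write_recording_csv", "read_recording_csv",
]
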