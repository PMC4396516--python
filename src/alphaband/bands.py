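"""Individually anchored EEG frequency bands and the alpha3/alpha2 ratio.

Two anchor frequencies are estimated per subject from the channel-averaged
("collapsed") spectrum: the individual alpha frequency (IAF), the frequency
of maximum power in the extended alpha range 5-14 Hz, and the theta/alpha
transition frequency (TF), the spectral trough below the alpha peak where
the theta and alpha spectra intersect.  The five subject-specific bands are
then

    delta  = [TF-4, TF-2)      theta  = [TF-2, TF)
    alpha1 = [TF, mid)         alpha2 = [mid, IAF)     alpha3 = [IAF, IAF+2]

with mid = (TF+IAF)/2, so alpha1 and alpha2 have equal width (IAF-TF)/2.
Relative power per bin is bin power divided by the mean power over 2-45 Hz;
a band's value is the mean of its bins' relative powers.  The ratio of
upper-alpha to mid-alpha relative power, alpha3/alpha2, stratifies subjects
into low (<1.00), middle ([1.00, 1.17)) and high (>=1.17) risk classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ValidationError
from .spectra import CollapsedSpectrum, FREQ_HI, FREQ_LO, FREQ_STEP, PowerSpectrum

#: Fixed risk-class boundaries for the alpha3/alpha2 ratio.
LOW_MIDDLE_CUTOFF = 1.00
MIDDLE_HIGH_CUTOFF = 1.17

#: Default TF search window: [3 Hz, IAF - 1 Hz].  The trough definition
#: ("minimum power in the alpha frequency range") leaves the window open;
#: this choice excludes the delta edge and forces TF < IAF.
TF_SEARCH_LO = 3.0
TF_SEARCH_GAP = 1.0

BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "alpha3")


class DegenerateAnchorsError(ValueError):
    """IAF and TF too close: the alpha sub-bands would collapse."""


@dataclass(frozen=True)
class AnchorFrequencies:
    """TF and IAF in Hz, plus quality flags from the detection heuristics.

    Flags: ``no-local-peak`` (the IAF bin is not a strict local maximum,
    e.g. argmax at a search edge of a monotone spectrum), ``flat-trough``
    (the TF minimum ties a neighboring bin), ``tf-at-search-edge``.
    """

    tf: float
    iaf: float
    quality_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 5.0 <= self.iaf <= 14.0:
            raise ValidationError("iaf must lie in [5, 14] Hz")
        if not self.tf < self.iaf:
            raise ValidationError("tf must be below iaf")


@dataclass(frozen=True)
class BandScheme:
    """The five contiguous individualized bands, half-open except alpha3."""

    tf: float
    iaf: float
    delta: tuple[float, float]
    theta: tuple[float, float]
    alpha1: tuple[float, float]
    alpha2: tuple[float, float]
    alpha3: tuple[float, float]
    truncated_delta: bool = False

    @property
    def mid(self) -> float:
        return (self.tf + self.iaf) / 2.0

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in BAND_NAMES}


@dataclass
class BandPowerProfile:
    """Per-band relative power, the alpha3/alpha2 ratio and the risk label."""

    relative_power: dict[str, float]
    alpha_ratio: float | None = None
    risk_label: str | None = None


def detect_anchors(cs: CollapsedSpectrum,
                   tf_search_lo: float = TF_SEARCH_LO,
                   tf_search_gap: float = TF_SEARCH_GAP) -> AnchorFrequencies:
    """Locate IAF (argmax in 5-14 Hz) and TF (argmin in [tf_search_lo, IAF-gap]).

    Among tied trough minima the highest frequency (closest to the alpha
    peak) wins.  Raises :class:`DegenerateAnchorsError` when IAF - TF < 1 Hz.
    """
    f, p = np.asarray(cs.freqs), np.asarray(cs.power)

    alpha_mask = (f >= 5.0) & (f <= 14.0)
    ai = np.flatnonzero(alpha_mask)
    iaf_idx = ai[np.argmax(p[ai])]
    iaf = float(f[iaf_idx])

    flags = set()
    is_local_max = (
        0 < iaf_idx < len(f) - 1
        and p[iaf_idx] > p[iaf_idx - 1] and p[iaf_idx] > p[iaf_idx + 1]
    )
    if not is_local_max:
        flags.add("no-local-peak")

    tf_mask = (f >= tf_search_lo) & (f <= iaf - tf_search_gap)
    ti = np.flatnonzero(tf_mask)
    if ti.size == 0:
        raise DegenerateAnchorsError(
            f"empty TF search window [{tf_search_lo}, {iaf - tf_search_gap}]")
    trough = p[ti].min()
    tied = ti[p[ti] == trough]
    tf_idx = int(tied[-1])  # tie-break: highest frequency
    tf = float(f[tf_idx])
    if tied.size > 1 or (tf_idx + 1 < len(p) and p[tf_idx + 1] == trough) \
            or (tf_idx - 1 >= 0 and p[tf_idx - 1] == trough):
        flags.add("flat-trough")
    if tf_idx == ti[0] or tf_idx == ti[-1]:
        flags.add("tf-at-search-edge")

    if iaf - tf < 1.0:
        raise DegenerateAnchorsError(
            f"iaf - tf = {iaf - tf:g} Hz < 1 Hz: band widths would collapse")
    return AnchorFrequencies(tf=tf, iaf=iaf, quality_flags=frozenset(flags))


def derive_bands(anchors: AnchorFrequencies) -> BandScheme:
    """Build the five band intervals from the anchors.

    Accepts off-grid anchors (e.g. cohort means).  When TF-4 would fall
    below the 2 Hz spectral floor, delta is truncated at 2 Hz and flagged.
    """
    tf, iaf = anchors.tf, anchors.iaf
    mid = (tf + iaf) / 2.0
    delta_lo = tf - 4.0
    truncated = delta_lo < FREQ_LO
    if truncated:
        delta_lo = FREQ_LO
    return BandScheme(
        tf=tf, iaf=iaf,
        delta=(delta_lo, tf - 2.0),
        theta=(tf - 2.0, tf),
        alpha1=(tf, mid),
        alpha2=(mid, iaf),
        alpha3=(iaf, iaf + 2.0),
        truncated_delta=truncated,
    )


def _band_bins(freqs: np.ndarray, interval: tuple[float, float],
               closed_right: bool) -> np.ndarray:
    lo, hi = interval
    eps = 1e-9
    if closed_right:
        return (freqs >= lo - eps) & (freqs <= hi + eps)
    return (freqs >= lo - eps) & (freqs < hi - eps)


def relative_band_power(spectrum: CollapsedSpectrum | PowerSpectrum,
                        scheme: BandScheme) -> BandPowerProfile:
    """Per-band relative power on the collapsed spectrum.

    Relative power per bin = bin power / mean power over all 2-45 Hz bins
    (so the grand mean of per-bin relative power is exactly 1); a band's
    value is the unweighted mean over the bins whose center frequency falls
    in its interval.  Intervals are half-open [lo, hi) except alpha3, which
    is closed at IAF+2 — the bin at exactly IAF belongs to alpha3.

    A :class:`PowerSpectrum` is collapsed (channel-averaged) first.
    """
    if isinstance(spectrum, PowerSpectrum):
        from .spectra import collapse

        spectrum = collapse(spectrum)
    f, p = np.asarray(spectrum.freqs), np.asarray(spectrum.power, dtype=float)
    mean_power = p.mean()
    if mean_power <= 0:
        raise ValidationError("spectrum has non-positive mean power")
    rel = p / mean_power

    powers: dict[str, float] = {}
    for name, interval in scheme.intervals().items():
        mask = _band_bins(f, interval, closed_right=(name == "alpha3"))
        if not mask.any():
            raise ValidationError(f"band {name} {interval} contains no bins")
        powers[name] = float(rel[mask].mean())
    profile = BandPowerProfile(relative_power=powers)
    profile.alpha_ratio = alpha_ratio(profile)
    profile.risk_label = classify_risk(profile.alpha_ratio)
    return profile


def alpha_ratio(profile: BandPowerProfile) -> float:
    """alpha3 relative power divided by alpha2 relative power."""
    a2 = profile.relative_power["alpha2"]
    a3 = profile.relative_power["alpha3"]
    if a2 <= 0:
        raise ValidationError("alpha2 relative power is zero: ratio undefined")
    return a3 / a2


def classify_risk(ratio: float) -> str:
    """Fixed-cutoff risk class: low < 1.00 <= middle < 1.17 <= high.

    The printed rule labels middle as ratios in [1, 1.16] and high as
    >= 1.17 at two-decimal precision; implementing middle as [1.00, 1.17)
    makes the partition total without contradicting any printed assignment.
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ValidationError("ratio must be finite and non-negative")
    if ratio < LOW_MIDDLE_CUTOFF:
        return "low"
    if ratio < MIDDLE_HIGH_CUTOFF:
        return "middle"
    return "high"


def tertile_split(ratios) -> tuple[float, float, list[str]]:
    """Data-driven alternative to the fixed cutoffs.

    Boundaries are the 1/3 and 2/3 empirical quantiles (linear interpolation
    of the empirical CDF); labels use the same [lo, hi) convention as
    :func:`classify_risk`.  Order-invariant.
    """
    values = np.asarray(list(ratios), dtype=float)
    if values.size < 3:
        raise ValidationError("tertile split needs >= 3 values")
    if np.ptp(values) == 0:
        raise ValidationError("all ratios identical: tertiles are degenerate")
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    labels = ["low" if v < q1 else ("middle" if v < q2 else "high")
              for v in values]
    return float(q1), float(q2), labels


__all__ = [
    "LOW_MIDDLE_CUTOFF", "MIDDLE_HIGH_CUTOFF", "BAND_NAMES",
    "AnchorFrequencies", "BandScheme", "BandPowerProfile",
    "DegenerateAnchorsError", "detect_anchors", "derive_bands",
    "relative_band_power", "alpha_ratio", "classify_risk", "tertile_split",
]
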