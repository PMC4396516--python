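"""ROI perfusion normalization, age-corrected W-scores, and a synthetic
cohort generator reproducing the study design's correlation structure.

SPECT tracer counts in each region of interest (ROI) are first normalized by
whole-cerebellum counts.  Because normalized perfusion declines with age, an
age-corrected *W-score* is computed against a healthy-control reference:

    W = (observed - (intercept + slope x age)) / residual_sd

where intercept/slope are the per-ROI ordinary-least-squares fit of
normalized perfusion on age in the control group and residual_sd is the
control residual standard deviation (n-2 denominator).  W behaves like a
z-score: controls score mean 0, sd 1, and a patient's W says how many
control-sds their perfusion deviates from the age-expected value.

The cohort generator emulates the study arms — a low-risk and a high-risk
group (split by the alpha3/alpha2 ratio at 1.17) plus healthy controls —
with a group-dependent correlation between theta relative power and
hippocampal-complex perfusion: negative in the low-risk group, positive in
the high-risk group, so that pooling the groups attenuates the correlation
toward zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ValidationError

#: ROI panel of the study configuration: five regions per hemisphere.
DEFAULT_ROIS = tuple(
    f"{region}_{side}"
    for region in ("frontal", "parietal", "temporal", "thalamus", "hippocampal_amygdalar")
    for side in ("left", "right")
)


@dataclass
class RoiPanel:
    """One subject's ROI counts plus the cerebellar normalization denominator."""

    subject_id: str
    roi_values: dict[str, float]
    cerebellum_counts: float | None
    age: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.roi_values.values()):
            raise ValidationError("all ROI counts must be > 0")


@dataclass
class ControlAgeModel:
    """Per-ROI linear age model fitted on normal controls."""

    intercept: dict[str, float]
    slope: dict[str, float]
    residual_sd: dict[str, float]
    n_controls: int
    degenerate: bool = False  # residual_sd ~ 0 somewhere (exact-line controls)

    def rois(self):
        return tuple(self.intercept)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ControlAgeModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def normalize_roi(panel: RoiPanel) -> RoiPanel:
    """Divide every ROI value by the whole-cerebellum counts."""
    if panel.normalized:
        return panel
    if panel.cerebellum_counts is None or panel.cerebellum_counts <= 0:
        raise ValidationError("cerebellum_counts must be > 0 for normalization")
    values = {k: v / panel.cerebellum_counts for k, v in panel.roi_values.items()}
    return RoiPanel(subject_id=panel.subject_id, roi_values=values,
                    cerebellum_counts=None, age=panel.age, normalized=True)


def fit_control_model(controls: list[RoiPanel]) -> ControlAgeModel:
    """OLS of normalized ROI value on age, per ROI, over the control group.

    Needs >= 3 controls with non-identical ages; residual_sd uses the n-2
    denominator.  Controls on an exact line (residual_sd ~ 0) are flagged
    degenerate rather than silently producing infinite W-scores.
    """
    if len(controls) < 3:
        raise ValidationError("control model needs >= 3 controls")
    controls = [normalize_roi(c) for c in controls]
    ages = np.array([c.age for c in controls], dtype=float)
    if np.ptp(ages) == 0:
        raise ValidationError("all control ages identical: singular age fit")
    rois = tuple(controls[0].roi_values)
    intercept, slope, resid_sd = {}, {}, {}
    degenerate = False
    n = len(controls)
    for roi in rois:
        y = np.array([c.roi_values[roi] for c in controls], dtype=float)
        fit = stats.linregress(ages, y)
        pred = fit.intercept + fit.slope * ages
        ss_res = float(np.sum((y - pred) ** 2))
        sd = float(np.sqrt(ss_res / (n - 2)))
        if sd < 1e-12:
            degenerate = True
        intercept[roi], slope[roi], resid_sd[roi] = float(fit.intercept), float(fit.slope), sd
    return ControlAgeModel(intercept=intercept, slope=slope,
                           residual_sd=resid_sd, n_controls=n,
                           degenerate=degenerate)


def w_score(subject: RoiPanel, model: ControlAgeModel) -> dict[str, float]:
    """Age-corrected W-score per ROI for one (normalized) subject panel."""
    subject = normalize_roi(subject)
    scores = {}
    for roi, value in subject.roi_values.items():
        if roi not in model.intercept:
            raise ValidationError(f"ROI '{roi}' missing from the control model")
        pred = model.intercept[roi] + model.slope[roi] * subject.age
        scores[roi] = (value - pred) / model.residual_sd[roi]
    return scores


# ---------------------------------------------------------------------------
# Synthetic cohort


@dataclass(frozen=True)
class CohortEffectConfig:
    """Generative effect sizes; defaults are the study conditions.

    Group means/SDs for ages, MMSE, hippocampal volumes and the Wahlund
    white-matter score are the printed cohort tables; the within-group
    theta-perfusion correlations are the printed Pearson r's (-0.544
    low-risk, +0.729 high-risk).  Theta relative-power levels and the
    normalized-perfusion scale are not printed and are set to realistic
    resting-state values (documented in the methods note).
    """

    r_theta_perfusion_low: float = -0.544
    r_theta_perfusion_high: float = 0.729
    age_mean_low: float = 69.1
    age_sd_low: float = 7.6
    age_mean_high: float = 70.6
    age_sd_high: float = 5.5
    age_mean_control: float = 70.0
    age_sd_control: float = 6.0
    mmse_mean_low: float = 27.9
    mmse_sd_low: float = 1.6
    mmse_mean_high: float = 27.2
    mmse_sd_high: float = 1.9
    hippo_left_mean_low: float = 2606.0
    hippo_left_sd_low: float = 353.0
    hippo_left_mean_high: float = 2073.0
    hippo_left_sd_high: float = 412.0
    hippo_right_mean_low: float = 2581.0
    hippo_right_sd_low: float = 473.0
    hippo_right_mean_high: float = 2296.0
    hippo_right_sd_high: float = 501.0
    wahlund_mean_low: float = 3.58
    wahlund_sd_low: float = 3.29
    wahlund_mean_high: float = 3.78
    wahlund_sd_high: float = 2.63
    # Not printed in the cohort tables; realistic resting-state choices.
    theta_mean_low: float = 0.06
    theta_mean_high: float = 0.09
    theta_sd: float = 0.02
    perfusion_intercept: float = 0.90  # normalized units at age 0 offsetting below
    perfusion_age_slope: float = -0.002  # per year
    perfusion_sd: float = 0.02
    perfusion_shift_high: float = -0.015  # high-risk hypoperfusion trend
    female_fraction_low: float = 6 / 14
    female_fraction_high: float = 9 / 13

    def __post_init__(self) -> None:
        for r in (self.r_theta_perfusion_low, self.r_theta_perfusion_high):
            if not -1.0 < r < 1.0:
                raise ValidationError("target correlations must lie in (-1, 1)")


def _correlated_pair(rng, n, r):
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return z1, z2


def generate_cohort(n_low: int = 14, n_high: int = 13, n_controls: int = 17,
                    effect_config: CohortEffectConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate subject-level records for the two patient groups + controls.

    Returns one row per subject with group, age, sex, MMSE, alpha3/alpha2
    ratio (drawn on the correct side of the 1.17 cutoff per group), theta
    relative power, normalized hippocampal-complex perfusion (age slope plus
    a residual correlated with theta at the group's target r), full ROI
    panels, hippocampal volumes and Wahlund score.  W-scores are *not*
    attached here; fit a control model and apply :func:`w_score`, so the
    generate -> fit -> score round trip exercises the real code path.
    """
    cfg = effect_config or CohortEffectConfig()
    if min(n_low, n_high, n_controls) < 2:
        raise ValidationError("every group needs n >= 2")
    rng = np.random.default_rng(seed)

    rows = []
    group_specs = [
        ("low-risk", n_low, cfg.age_mean_low, cfg.age_sd_low, cfg.r_theta_perfusion_low,
         cfg.theta_mean_low, 0.0),
        ("high-risk", n_high, cfg.age_mean_high, cfg.age_sd_high, cfg.r_theta_perfusion_high,
         cfg.theta_mean_high, cfg.perfusion_shift_high),
        ("control", n_controls, cfg.age_mean_control, cfg.age_sd_control, 0.0,
         cfg.theta_mean_low, 0.0),
    ]
    sid = 0
    for group, n, age_mu, age_sd, r, theta_mu, perf_shift in group_specs:
        ages = rng.normal(age_mu, age_sd, n)
        z_theta, z_perf = _correlated_pair(rng, n, r)
        theta = theta_mu + cfg.theta_sd * z_theta
        hip_perf = (cfg.perfusion_intercept + cfg.perfusion_age_slope * ages
                    + perf_shift + cfg.perfusion_sd * z_perf)
        if group == "low-risk":
            ratio = rng.uniform(0.77, 1.16, n)
            sex = rng.random(n) < cfg.female_fraction_low
            mmse = rng.normal(cfg.mmse_mean_low, cfg.mmse_sd_low, n)
            hl = rng.normal(cfg.hippo_left_mean_low, cfg.hippo_left_sd_low, n)
            hr = rng.normal(cfg.hippo_right_mean_low, cfg.hippo_right_sd_low, n)
            wah = rng.normal(cfg.wahlund_mean_low, cfg.wahlund_sd_low, n)
        elif group == "high-risk":
            ratio = rng.uniform(1.17, 1.52, n)
            sex = rng.random(n) < cfg.female_fraction_high
            mmse = rng.normal(cfg.mmse_mean_high, cfg.mmse_sd_high, n)
            hl = rng.normal(cfg.hippo_left_mean_high, cfg.hippo_left_sd_high, n)
            hr = rng.normal(cfg.hippo_right_mean_high, cfg.hippo_right_sd_high, n)
            wah = rng.normal(cfg.wahlund_mean_high, cfg.wahlund_sd_high, n)
        else:
            ratio = np.full(n, np.nan)
            sex = rng.random(n) < 0.5
            mmse = rng.normal(29.0, 1.0, n)
            hl = rng.normal(2900.0, 300.0, n)
            hr = rng.normal(2900.0, 300.0, n)
            wah = rng.normal(1.0, 1.0, n)

        for i in range(n):
            row = {
                "subject_id": f"S{sid:04d}",
                "group": group,
                "age": float(ages[i]),
                "sex": "F" if sex[i] else "M",
                "mmse": float(np.clip(mmse[i], 0, 30)),
                "alpha_ratio": float(ratio[i]) if np.isfinite(ratio[i]) else np.nan,
                "theta_rel_power": float(max(theta[i], 1e-4)),
                "hippocampal_volume_left": float(hl[i]),
                "hippocampal_volume_right": float(hr[i]),
                "wahlund_score": float(np.clip(wah[i], 0, None)),
            }
            for roi in DEFAULT_ROIS:
                if roi.startswith("hippocampal_amygdalar"):
                    val = hip_perf[i]
                else:
                    val = (cfg.perfusion_intercept
                           + cfg.perfusion_age_slope * ages[i] + perf_shift
                           + cfg.perfusion_sd * rng.standard_normal())
                row[f"perfusion_{roi}"] = float(max(val, 1e-3))
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)


def panels_from_cohort(df: pd.DataFrame) -> list[RoiPanel]:
    """Extract (already normalized) ROI panels from a cohort table."""
    panels = []
    for _, row in df.iterrows():
        values = {roi: row[f"perfusion_{roi}"] for roi in DEFAULT_ROIS}
        panels.append(RoiPanel(subject_id=row["subject_id"], roi_values=values,
                               cerebellum_counts=None, age=row["age"],
                               normalized=True))
    return panels


def attach_w_scores(df: pd.DataFrame, model: ControlAgeModel | None = None) -> pd.DataFrame:
    """Fit the control model on the cohort's control rows (unless given) and
    append one ``w_<roi>`` column per ROI for every subject."""
    if model is None:
        controls = panels_from_cohort(df[df["group"] == "control"])
        model = fit_control_model(controls)
    out = df.copy()
    scores = [w_score(p, model) for p in panels_from_cohort(df)]
    for roi in model.rois():
        out[f"w_{roi}"] = [s[roi] for s in scores]
    return out


__all__ = [
    "DEFAULT_ROIS", "RoiPanel", "ControlAgeModel", "CohortEffectConfig",
    "normalize_roi", "fit_control_model", "w_score",
    "generate_cohort", "panels_from_cohort", "attach_w_scores",
]
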