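"""Synthetic sleep-recording cohort generator.

Real overnight recordings for OSA severity modeling are not publicly
deposited, so every downstream stage is exercised against a generator that
emulates the *statistical structure* of such data:

* RR-interval series whose slow apnea-linked cyclic oscillation (period
  30-60 s, i.e. VLF-band power) grows with severity, on top of respiratory
  and baroreflex-like sinusoidal modulation and white short-term
  variability that shrinks with severity;
* isolated ectopic-like artifacts injected at a configurable rate
  (0.5x or 1.5x the local interval) as targets for the correction stage;
* SpO2 traces with square desaturation dips whose rate follows the AHI and
  whose depth grows with severity, plus measurement noise, clipped to
  [40, 100]%;
* anthropometrics drawn from truncated normals centered on class-typical
  medians (BMI and age shift upward with severity; the male fraction
  rises).

The per-class parameter defaults are engineering choices that reproduce the
*direction* of the clinical contrasts (e.g. T90 near zero for normal
subjects and large for severe ones), not claims about physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rri_preprocess import RRiSeries
from .spo2_metrics import SpO2Trace

__all__ = [
    "SEVERITY_CLASSES",
    "SeverityEffects",
    "CohortSpec",
    "SubjectRecord",
    "classify_severity",
    "binary_label",
    "generate_cohort",
    "DEFAULT_EFFECTS",
]

SEVERITY_CLASSES = ["normal", "mild", "moderate", "severe"]

# AHI class boundaries, events/h, half-open [lo, hi)
_AHI_EDGES = {"normal": (0.0, 5.0), "mild": (5.0, 15.0),
              "moderate": (15.0, 30.0), "severe": (30.0, float("inf"))}


def classify_severity(ahi: float) -> str:
    """Map an apnea-hypopnea index (events/h) to a severity class.

    Boundaries are half-open: AHI of exactly 5, 15 or 30 falls in the
    higher class.
    """
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


def binary_label(ahi: float) -> str:
    """Dichotomize at the clinical AHI cutoff of 15 events/h."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    return "normal-to-mild" if ahi < 15 else "moderate-to-severe"


@dataclass(frozen=True)
class SeverityEffects:
    """Generative parameters for one severity class.

    ahi_range : events/h, sampled uniformly; must respect the class edges.
    cyclic_amp_ms : amplitude of the slow apnea-linked RR oscillation.
    cyclic_period_s : period of that oscillation (apnea cycle length).
    white_sd_ms : SD of beat-to-beat white variability.
    desat_rate_frac : desaturation events per hour as a fraction of AHI.
    desat_depth_pct : mean depth of a desaturation dip, % saturation.
    bmi_median / age_median / male_frac : anthropometric centers.
    """

    ahi_range: tuple[float, float]
    cyclic_amp_ms: float
    cyclic_period_s: float = 45.0
    white_sd_ms: float = 25.0
    desat_rate_frac: float = 0.6
    desat_rate_per_hour: float | None = None  # overrides desat_rate_frac * AHI
    desat_depth_pct: float = 4.0
    bmi_median: float = 27.0
    age_median: float = 45.0
    male_frac: float = 0.3


DEFAULT_EFFECTS: dict[str, SeverityEffects] = {
    # centers follow the typical clinical contrasts between severity groups
    "normal": SeverityEffects(ahi_range=(0.5, 5.0), cyclic_amp_ms=5.0,
                              white_sd_ms=30.0, desat_depth_pct=2.5,
                              bmi_median=26.7, age_median=41.0, male_frac=0.255),
    "mild": SeverityEffects(ahi_range=(5.0, 15.0), cyclic_amp_ms=18.0,
                            white_sd_ms=27.0, desat_depth_pct=4.5,
                            bmi_median=31.0, age_median=52.0, male_frac=0.429),
    "moderate": SeverityEffects(ahi_range=(15.0, 30.0), cyclic_amp_ms=32.0,
                                white_sd_ms=24.0, desat_depth_pct=6.5,
                                bmi_median=31.0, age_median=56.5, male_frac=0.429),
    "severe": SeverityEffects(ahi_range=(30.0, 80.0), cyclic_amp_ms=55.0,
                              white_sd_ms=20.0, desat_depth_pct=10.5,
                              bmi_median=34.7, age_median=56.0, male_frac=0.441),
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort.

    n_per_class : subjects generated per severity class.
    hours : recording hours per subject.
    seed : RNG seed; the cohort is a pure function of the spec.
    artifact_rate : fraction of beats replaced by ectopic-like values.
    severity_effects : per-class generative parameters.
    """

    n_per_class: int = 10
    hours: int = 6
    seed: int = 0
    artifact_rate: float = 0.01
    spo2_hz: float = 1.0
    severity_effects: dict[str, SeverityEffects] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.hours < 1:
            raise ValueError("hours must be >= 1")
        if not 0.0 <= self.artifact_rate <= 0.1:
            raise ValueError("artifact_rate must lie in [0, 0.1]")
        for cls in SEVERITY_CLASSES:
            if cls not in self.severity_effects:
                raise ValueError(f"severity_effects missing class {cls!r}")
            lo, hi = self.severity_effects[cls].ahi_range
            edge_lo, edge_hi = _AHI_EDGES[cls]
            if lo < edge_lo or hi > edge_hi or lo >= hi:
                raise ValueError(
                    f"AHI range {lo}-{hi} violates the {cls} class "
                    f"boundaries [{edge_lo}, {edge_hi})"
                )


@dataclass
class SubjectRecord:
    """One synthetic subject: anthropometrics, AHI, signals."""

    id: str
    gender: str            # "male" | "female"
    age: float             # years
    height: float          # m
    weight: float          # kg
    bmi: float             # kg/m^2
    ahi: float             # events/h
    severity: str
    rri_hours: list[RRiSeries]
    spo2: SpO2Trace

    def __post_init__(self) -> None:
        if abs(self.bmi - self.weight / self.height**2) > 0.1:
            raise ValueError("BMI inconsistent with weight/height^2")
        if self.severity != classify_severity(self.ahi):
            raise ValueError("severity label inconsistent with AHI")


def _truncated_normal(rng: np.random.Generator, center: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(center, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(center, lo, hi))


def _make_rri_hour(rng: np.random.Generator, eff: SeverityEffects,
                   base_rr: float, hour: int, artifact_rate: float) -> RRiSeries:
    """One hour of beats: base + respiratory + baroreflex-like + slow cyclic
    modulation + white noise, with isolated ectopic-like artifacts."""
    duration = 3600.0
    n = int(duration / (base_rr / 1000.0)) + 8
    # nominal beat times for the modulation argument; the sub-second phase
    # error of using the nominal grid is negligible at these periods
    t = np.arange(n) * base_rr / 1000.0
    resp = 12.0 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    lf = 10.0 * np.sin(2 * np.pi * 0.095 * t + rng.uniform(0, 2 * np.pi))
    # amplitude-modulated apnea-linked oscillation in the VLF band
    am = 1.0 + 0.3 * np.sin(2 * np.pi * t / 600.0 + rng.uniform(0, 2 * np.pi))
    cyc = eff.cyclic_amp_ms * am * np.sin(
        2 * np.pi * t / eff.cyclic_period_s + rng.uniform(0, 2 * np.pi)
    )
    noise = rng.normal(0.0, eff.white_sd_ms, n)
    rr = base_rr + resp + lf + cyc + noise
    rr = np.clip(rr, 300.0, 2000.0)
    # truncate to the hour
    cum = np.cumsum(rr) / 1000.0
    rr = rr[cum <= duration]
    if artifact_rate > 0:
        n_art = rng.binomial(len(rr), artifact_rate)
        if n_art > 0:
            idx = rng.choice(np.arange(1, len(rr) - 1), size=n_art, replace=False)
            factor = rng.choice([0.5, 1.5], size=n_art)
            rr[idx] = rr[idx] * factor
    return RRiSeries(values=rr, t_start=hour * 3600.0)


def _make_spo2(rng: np.random.Generator, eff: SeverityEffects, ahi: float,
               hours: int, fs: float) -> SpO2Trace:
    """Overnight saturation: baseline with square desaturation dips."""
    n = int(hours * 3600 * fs)
    baseline = rng.uniform(95.0, 98.0)
    sat = np.full(n, baseline)
    rate = (eff.desat_rate_per_hour if eff.desat_rate_per_hour is not None
            else eff.desat_rate_frac * ahi)
    n_events = rng.poisson(rate * hours)
    for _ in range(n_events):
        depth = max(0.5, rng.normal(eff.desat_depth_pct, 2.0))
        dur = int(rng.uniform(15, 45) * fs)
        start = rng.integers(0, max(1, n - dur))
        sat[start:start + dur] = np.minimum(sat[start:start + dur], baseline - depth)
    sat = sat + rng.normal(0.0, 0.3, n)
    return SpO2Trace(sat=np.clip(sat, 40.0, 100.0), sample_hz=fs)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate ``4 * n_per_class`` subjects, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectRecord] = []
    for cls in SEVERITY_CLASSES:
        eff = spec.severity_effects[cls]
        for i in range(spec.n_per_class):
            lo, hi = eff.ahi_range
            # margin keeps the 1-decimal rounding inside the class interval
            ahi = round(float(rng.uniform(lo, hi - 0.1)), 1)
            gender = "male" if rng.uniform() < eff.male_frac else "female"
            height = round(_truncated_normal(
                rng, 1.74 if gender == "male" else 1.62, 0.07, 1.45, 2.00), 2)
            bmi = _truncated_normal(rng, eff.bmi_median, 4.0, 17.0, 55.0)
            weight = round(bmi * height**2, 1)
            age = round(_truncated_normal(rng, eff.age_median, 11.0, 18.0, 90.0))
            base_rr = rng.uniform(700.0, 1000.0)
            # subject-level heterogeneity: individuals of the same severity
            # differ in oscillation amplitude and short-term variability
            eff_subj = replace(
                eff,
                cyclic_amp_ms=eff.cyclic_amp_ms * float(np.exp(rng.normal(0, 0.25))),
                white_sd_ms=eff.white_sd_ms * float(np.exp(rng.normal(0, 0.15))),
            )
            rri_hours = [
                _make_rri_hour(rng, eff_subj, base_rr, h, spec.artifact_rate)
                for h in range(spec.hours)
            ]
            spo2 = _make_spo2(rng, eff, ahi, spec.hours, spec.spo2_hz)
            subjects.append(SubjectRecord(
                id=f"{cls[:3]}-{i:03d}",
                gender=gender,
                age=float(age),
                height=height,
                weight=weight,
                bmi=round(weight / height**2, 2),
                ahi=ahi,
                severity=cls,
                rri_hours=rri_hours,
                spo2=spo2,
            ))
    return subjects


def null_effects() -> dict[str, SeverityEffects]:
    """Severity effects switched OFF: every class shares the 'mild' signal
    parameters and anthropometric centers, and the desaturation rate is
    pinned to a common constant instead of following the AHI, so
    class-conditional feature distributions coincide and only the AHI label
    differs.  Used for null-calibration experiments."""
    ref = DEFAULT_EFFECTS["mild"]
    return {
        cls: replace(ref, ahi_range=DEFAULT_EFFECTS[cls].ahi_range
                     if cls != "severe" else (30.0, 80.0),
                     desat_rate_per_hour=6.0)
        for cls in SEVERITY_CLASSES
    }
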