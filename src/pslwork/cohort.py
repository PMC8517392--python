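"""Synthetic two-group (normal control vs type 2 diabetes) cohort generator.

Real strain traces and clinical covariates from the study population this
package models are not redistributable, so every downstream stage is
exercised on synthetic cohorts whose statistical structure mirrors a
published 50-vs-50 control/T2DM echocardiographic comparison:

* covariates are drawn per subject from normal (mean/SD) or log-normal
  (median/IQR) distributions, with Bernoulli sex and smoking status and
  physiologic truncation by resampling;
* each subject receives 17 segmental longitudinal strain traces built
  from smooth raised-cosine contraction profiles, valve-event timings and
  a cuff pressure, with the diabetic phenotype showing reduced peak
  strain and more frequent post-systolic shortening;
* a disease-severity latent score — a weighted sum of z-scored HbA1c and
  z-scored log(1 + diabetes duration) plus noise — scales peak strain
  downward, embedding negative glycemia -> myocardial-work effects with
  configurable standardized magnitudes.

Reproducibility: a single master seed; each subject draws from its own
substream keyed by a stable hash of the subject id, so results do not
depend on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pressure import (
    RAISED_COSINE_TEMPLATE,
    CuffPressure,
    ValveEvents,
    scale_to_cycle,
)
from .work import (
    N_SEGMENTS,
    GlobalWorkSet,
    SegmentWork,
    StrainTrace,
    aggregate_global,
    peak_systolic_strain,
    segment_work_matrix,
)

__all__ = [
    "NormalDist",
    "LogNormalDist",
    "BernoulliDist",
    "PhenotypeSpec",
    "GroupSpec",
    "SubjectRecord",
    "nc_group_spec",
    "t2dm_group_spec",
    "sample_covariates",
    "sample_traces",
    "generate_cohort",
    "records_to_frame",
]

_Z75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class NormalDist:
    """Normal covariate, truncated to [lo, hi] by resampling."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"sd must be > 0, got {self.sd}")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise ValidationError(f"truncation bounds reject virtually all mass: {self}")

    def zscore(self, x: float) -> float:
        return (x - self.mean) / self.sd


@dataclass(frozen=True)
class LogNormalDist:
    """Log-normal covariate parameterized by its median and IQR.

    ``mu = ln(median)`` and ``sigma`` solves
    ``IQR = 2 * median * sinh(z75 * sigma)``, matching both printed
    summaries exactly.
    """

    median: float
    iqr: float

    def __post_init__(self) -> None:
        if not (self.median > 0 and self.iqr > 0):
            raise ValidationError("median and IQR must be positive")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        return float(np.arcsinh(self.iqr / (2.0 * self.median)) / _Z75)

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.normal(self.mu, self.sigma)))

    def log1p_moments(self) -> tuple[float, float]:
        """Population mean and SD of log(1 + X) by Gauss-Hermite quadrature."""
        z, wts = np.polynomial.hermite_e.hermegauss(96)
        wts = wts / wts.sum()
        g = np.log1p(np.exp(self.mu + self.sigma * z))
        m = float(wts @ g)
        v = float(wts @ (g - m) ** 2)
        return m, float(np.sqrt(v))

    def zscore(self, x: float) -> float:
        m, s = self.log1p_moments()
        return (np.log1p(x) - m) / s


@dataclass(frozen=True)
class BernoulliDist:
    """Binary covariate (0/1) with success probability p."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"probability outside [0, 1]: {self.p}")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.random() < self.p)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Strain/timing phenotype of one group.

    ``peak_strain_pct`` is the group-mean peak systolic strain magnitude;
    per-subject magnitude is ``peak_strain_pct * (1 + strain_rel_sd * u)``
    with the unit-variance severity score ``u`` (negative effect loadings
    reduce strain as the covariate rises).  ``severity_effects`` maps
    covariate names to configured standardized effects *on the work
    outcome scale*; the generator rescales them into latent loadings,
    compensating the dilution its other variance channels (cuff-pressure
    scaling, segment heterogeneity) would otherwise cause, so regression
    of constructive work on the covariates over a large sample recovers
    the configured values.
    """

    peak_strain_pct: float  # group-mean |peak systolic strain|
    strain_rel_sd: float = 0.12  # relative SD of subject strain magnitude
    segment_cv: float = 0.10  # inter-segment heterogeneity (CV)
    releng_frac_mean: float = 0.15  # strain recovered during IVR, fraction of peak
    releng_frac_sd: float = 0.03
    pss_prob: float = 0.5  # probability a segment shows post-systolic shortening
    pss_magnitude_pct: float = 1.5  # PSS bump depth in strain %
    ivc_s: tuple[float, float] = (0.065, 0.006)  # (mean, sd) phase durations
    ejection_s: tuple[float, float] = (0.305, 0.020)
    ivr_s: tuple[float, float] = (0.075, 0.008)
    trace_hz: float = 150.0  # sampling rate of the exported strain traces
    severity_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pss_prob <= 1.0:
            raise ValidationError("pss_prob must be in [0, 1]")
        load = sum(b * b for b in self.severity_effects.values())
        if load > 1.0:
            raise ValidationError(
                f"severity loadings overdetermined: sum of squares {load} > 1"
            )


#: Relative outcome variance contributed by relengthening, post-systolic
#: shortening and valve-timing variability (small, approximately constant).
_MISC_REL_VAR = 0.001


@dataclass(frozen=True)
class GroupSpec:
    """Sampling specification of one study arm."""

    label: str
    n: int
    covariates: Mapping[str, object]  # name -> distribution
    phenotype: PhenotypeSpec

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group needs n >= 2 subjects, got {self.n}")
        for name in self.phenotype.severity_effects:
            if name not in self.covariates:
                raise ValidationError(
                    f"severity effect refers to unknown covariate {name!r}"
                )
        self.severity_loadings()  # fail early if loadings are overdetermined

    def attenuation(self) -> float:
        """Fraction of a configured outcome effect the strain channel carries.

        Work scales with the strain-magnitude channel (relative SD
        ``strain_rel_sd``) but also varies with cuff SBP, segment
        heterogeneity (averaged over 17 segments) and minor timing/shape
        channels, which dilute a standardized effect routed through
        strain by ``strain_rel_sd / total relative SD``.
        """
        ph = self.phenotype
        v_extra = ph.segment_cv**2 / N_SEGMENTS + _MISC_REL_VAR
        sbp = self.covariates.get("sbp_mmhg")
        if isinstance(sbp, NormalDist):
            v_extra += (sbp.sd / sbp.mean) ** 2
        return float(ph.strain_rel_sd / np.sqrt(ph.strain_rel_sd**2 + v_extra))

    def severity_loadings(self) -> dict[str, float]:
        """Latent loadings delivering the configured outcome-scale effects."""
        kappa = self.attenuation()
        lam = {k: b / kappa for k, b in self.phenotype.severity_effects.items()}
        ss = sum(v * v for v in lam.values())
        if ss > 1.0:
            raise ValidationError(
                "configured severity effects too large for the strain channel: "
                f"attenuation-corrected loadings have sum of squares {ss:.3f} > 1"
            )
        return lam


@dataclass
class SubjectRecord:
    """One synthetic subject: identity, covariates and (later) outcomes."""

    subject_id: str
    group: str
    covariates: dict[str, float]
    outcomes: GlobalWorkSet | None = None


def _default_nc_covariates() -> dict[str, object]:
    return {
        "male": BernoulliDist(0.58),
        "smoking": BernoulliDist(0.24),
        "age_yr": NormalDist(46.88, 10.60, lo=18, hi=80),
        "bmi_kg_m2": NormalDist(24.32, 3.67, lo=15, hi=45),
        "bsa_m2": NormalDist(1.72, 0.16, lo=1.2, hi=2.6),
        "sbp_mmhg": NormalDist(118.84, 3.94, lo=90, hi=140),
        "dbp_mmhg": NormalDist(77.70, 6.31, lo=50, hi=95),
        "heart_rate_bpm": NormalDist(67.82, 8.37, lo=45, hi=110),
        "tc_mmol_l": NormalDist(4.33, 0.61, lo=2, hi=9),
        "tg_mmol_l": NormalDist(1.65, 0.64, lo=0.3, hi=8),
        "hdl_mmol_l": LogNormalDist(1.01, 0.30),
        "ldl_mmol_l": NormalDist(2.48, 0.70, lo=0.5, hi=6),
        "hba1c_pct": NormalDist(5.24, 0.36, lo=4, hi=15),
        "lvef_pct": NormalDist(63.0, 2.5, lo=50, hi=75),
        "lvedv_ml": NormalDist(97.4, 11.6, lo=60, hi=160),
    }


def _default_t2dm_covariates() -> dict[str, object]:
    cov = _default_nc_covariates()
    cov.update(
        {
            "male": BernoulliDist(0.52),
            "smoking": BernoulliDist(0.28),
            "age_yr": NormalDist(50.20, 9.73, lo=18, hi=80),
            "bmi_kg_m2": NormalDist(26.09, 3.80, lo=15, hi=45),
            "bsa_m2": NormalDist(1.83, 0.24, lo=1.2, hi=2.6),
            "sbp_mmhg": NormalDist(120.68, 6.00, lo=90, hi=140),
            "dbp_mmhg": NormalDist(79.24, 7.40, lo=50, hi=95),
            "heart_rate_bpm": NormalDist(71.02, 9.41, lo=45, hi=110),
            "tc_mmol_l": NormalDist(4.50, 1.01, lo=2, hi=9),
            "tg_mmol_l": NormalDist(2.17, 1.04, lo=0.3, hi=8),
            "hdl_mmol_l": LogNormalDist(1.03, 0.23),
            "ldl_mmol_l": NormalDist(2.79, 0.66, lo=0.5, hi=6),
            "hba1c_pct": NormalDist(8.06, 1.37, lo=4, hi=15),
            # diabetes-only laboratory values and history
            "fpg_mmol_l": NormalDist(7.88, 1.49, lo=3.5, hi=16),
            "ppg2h_mmol_l": NormalDist(11.60, 2.32, lo=4, hi=25),
            "diabetes_duration_yr": LogNormalDist(2.50, 9.37),
        }
    )
    return cov


def nc_group_spec(n: int = 50) -> GroupSpec:
    """Default normal-control arm: preserved strain, no severity effects."""
    return GroupSpec(
        label="NC",
        n=n,
        covariates=_default_nc_covariates(),
        phenotype=PhenotypeSpec(peak_strain_pct=19.5, pss_prob=0.50,
                                pss_magnitude_pct=2.15),
    )


def t2dm_group_spec(n: int = 50) -> GroupSpec:
    """Default diabetic arm: depressed strain driven by glycemia and duration."""
    return GroupSpec(
        label="T2DM",
        n=n,
        covariates=_default_t2dm_covariates(),
        phenotype=PhenotypeSpec(
            peak_strain_pct=17.0,
            pss_prob=0.65,
            pss_magnitude_pct=2.2,
            severity_effects={"hba1c_pct": -0.45, "diabetes_duration_yr": -0.30},
        ),
    )


def _subject_rng(seed: int, subject_id: str, stream: int) -> np.random.Generator:
    """Substream for one subject, keyed by a stable hash of its id."""
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, stream)))


def sample_covariates(spec: GroupSpec, seed: int) -> list[SubjectRecord]:
    """Draw ``spec.n`` subjects' covariates; outcomes are left empty."""
    records = []
    for i in range(spec.n):
        sid = f"{spec.label}-{i + 1:04d}"
        rng = _subject_rng(seed, sid, stream=0)
        cov: dict[str, float] = {}
        # canonical (sorted) draw order, so equivalent specs built with
        # different dict insertion orders sample identically
        for name in sorted(spec.covariates):
            cov[name] = spec.covariates[name].sample(rng)
        # keep the cuff reading physiologic: systolic above diastolic
        while cov["sbp_mmhg"] <= cov["dbp_mmhg"] + 10.0:
            cov["sbp_mmhg"] = spec.covariates["sbp_mmhg"].sample(rng)
            cov["dbp_mmhg"] = spec.covariates["dbp_mmhg"].sample(rng)
        records.append(SubjectRecord(subject_id=sid, group=spec.label, covariates=cov))
    return records


def _severity_score(
    record: SubjectRecord, spec: GroupSpec, rng: np.random.Generator
) -> float:
    """Unit-variance latent severity: covariate loadings plus residual noise."""
    loadings = spec.severity_loadings()
    u = 0.0
    for name in sorted(loadings):
        u += loadings[name] * spec.covariates[name].zscore(record.covariates[name])
    noise_sd = float(np.sqrt(1.0 - sum(v * v for v in loadings.values())))
    return u + noise_sd * rng.standard_normal()


def _draw_valve_events(
    ph: PhenotypeSpec, rng: np.random.Generator
) -> ValveEvents:
    for _ in range(100):
        ivc = rng.normal(*ph.ivc_s)
        ej = rng.normal(*ph.ejection_s)
        ivr = rng.normal(*ph.ivr_s)
        if min(ivc, ej, ivr) > 0.02:
            return ValveEvents(0.0, ivc, ivc + ej, ivc + ej + ivr)
    raise ValidationError("valve-timing spec rejects virtually all draws")


def _strain_matrix(
    events: ValveEvents,
    peaks: np.ndarray,
    releng: float,
    pss_mask: np.ndarray,
    pss_mag: float,
    trace_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine strain profiles for all 17 segments on one time grid.

    Flat during isovolumic contraction, half-cosine shortening to the
    segmental peak at aortic valve closure, partial half-cosine
    relengthening during isovolumic relaxation; segments flagged in
    ``pss_mask`` additionally shorten and recover mid-IVR (post-systolic
    shortening), which is the wasted-work substrate.
    """
    n = max(int(round(events.t_mvo * trace_hz)) + 1, 24)
    t = np.linspace(0.0, events.t_mvo, n)
    eps = np.zeros((peaks.size, n))

    sys_m = (t >= events.t_avo) & (t <= events.t_avc)
    x = (t[sys_m] - events.t_avo) / (events.t_avc - events.t_avo)
    eps[:, sys_m] = -peaks[:, None] * 0.5 * (1.0 - np.cos(np.pi * x))

    ivr_m = t > events.t_avc
    y = (t[ivr_m] - events.t_avc) / (events.t_mvo - events.t_avc)
    base = -peaks[:, None] + releng * peaks[:, None] * 0.5 * (1.0 - np.cos(np.pi * y))
    bump = -pss_mag * np.sin(np.pi * y)[None, :] * pss_mask[:, None]
    eps[:, ivr_m] = base + bump
    return t, eps


def sample_traces(
    record: SubjectRecord, spec: GroupSpec, seed: int
) -> tuple[list[StrainTrace], ValveEvents, CuffPressure]:
    """Simulate one subject's 17 strain traces, valve events and cuff pressure."""
    rng = _subject_rng(seed, record.subject_id, stream=1)
    ph = spec.phenotype
    events = _draw_valve_events(ph, rng)
    cuff = CuffPressure(
        sbp=record.covariates["sbp_mmhg"], dbp=record.covariates["dbp_mmhg"]
    )

    u = _severity_score(record, spec, rng)
    subject_peak = ph.peak_strain_pct * max(1.0 + ph.strain_rel_sd * u, 0.2)
    seg_factor = np.clip(
        1.0 + ph.segment_cv * rng.standard_normal(N_SEGMENTS), 0.3, 1.7
    )
    peaks = subject_peak * seg_factor
    releng = float(np.clip(rng.normal(ph.releng_frac_mean, ph.releng_frac_sd),
                           0.02, 0.6))
    pss_mask = (rng.random(N_SEGMENTS) < ph.pss_prob).astype(float)

    t, eps = _strain_matrix(events, peaks, releng, pss_mask,
                            ph.pss_magnitude_pct, ph.trace_hz)
    traces = [
        StrainTrace(segment_id=i + 1, times=t, strain=eps[i]) for i in range(N_SEGMENTS)
    ]
    return traces, events, cuff


@dataclass
class SubjectBundle:
    """Everything generated for one subject."""

    record: SubjectRecord
    traces: list[StrainTrace]
    events: ValveEvents
    cuff: CuffPressure


def _compute_outcomes(bundle: SubjectBundle, n_grid: int) -> GlobalWorkSet:
    pressure = scale_to_cycle(RAISED_COSINE_TEMPLATE, bundle.events, bundle.cuff)
    strain = np.vstack([tr.strain for tr in bundle.traces])
    wi, cw, ww = segment_work_matrix(
        strain, bundle.traces[0].times, pressure, bundle.events, n_grid=n_grid
    )
    peaks = [peak_systolic_strain(tr, bundle.events) for tr in bundle.traces]
    seg_works = [
        SegmentWork(i + 1, float(wi[i]), float(cw[i]), float(ww[i]))
        for i in range(N_SEGMENTS)
    ]
    return aggregate_global(seg_works, peaks)


def generate_cohort(
    nc_spec: GroupSpec | None = None,
    dm_spec: GroupSpec | None = None,
    seed: int = 0,
    n_grid: int = 1000,
) -> tuple[pd.DataFrame, dict[str, SubjectBundle]]:
    """Generate a full two-arm cohort with computed work outcomes.

    Returns the cohort table (one row per subject: covariates, derived
    pulse pressure, and the five global work indices) and a mapping from
    subject id to its trace bundle.  Deterministic given ``seed``.
    """
    nc_spec = nc_spec if nc_spec is not None else nc_group_spec()
    dm_spec = dm_spec if dm_spec is not None else t2dm_group_spec()
    bundles: dict[str, SubjectBundle] = {}
    for spec in (nc_spec, dm_spec):
        for record in sample_covariates(spec, seed):
            traces, events, cuff = sample_traces(record, spec, seed)
            bundle = SubjectBundle(record, traces, events, cuff)
            record.outcomes = _compute_outcomes(bundle, n_grid=n_grid)
            bundles[record.subject_id] = bundle
    table = records_to_frame([b.record for b in bundles.values()])
    return table, bundles


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the cohort covariate/outcome table."""
    rows = []
    for r in records:
        row: dict[str, object] = {"subject_id": r.subject_id, "group": r.group}
        row.update(r.covariates)
        if "sbp_mmhg" in r.covariates and "dbp_mmhg" in r.covariates:
            row["pulse_pressure_mmhg"] = (
                r.covariates["sbp_mmhg"] - r.covariates["dbp_mmhg"]
            )
        if r.outcomes is not None:
            row.update(
                gls_pct=r.outcomes.gls,
                gwi_mmhg_pct=r.outcomes.gwi,
                gcw_mmhg_pct=r.outcomes.gcw,
                gww_mmhg_pct=r.outcomes.gww,
                gwe_pct=r.outcomes.gwe,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structured-text (YAML) group specifications

def _dist_to_dict(dist) -> dict:
    if isinstance(dist, NormalDist):
        d = {"type": "normal", "mean": dist.mean, "sd": dist.sd}
        if np.isfinite(dist.lo):
            d["lo"] = dist.lo
        if np.isfinite(dist.hi):
            d["hi"] = dist.hi
        return d
    if isinstance(dist, LogNormalDist):
        return {"type": "lognormal", "median": dist.median, "iqr": dist.iqr}
    if isinstance(dist, BernoulliDist):
        return {"type": "bernoulli", "p": dist.p}
    raise ValidationError(f"unknown distribution object {dist!r}")


def _dist_from_dict(d: Mapping) -> object:
    kind = dict(d).pop("type", None)
    args = {k: v for k, v in d.items() if k != "type"}
    if kind == "normal":
        return NormalDist(**args)
    if kind == "lognormal":
        return LogNormalDist(**args)
    if kind == "bernoulli":
        return BernoulliDist(**args)
    raise ValidationError(f"unknown distribution type {kind!r}")


def spec_to_dict(spec: GroupSpec) -> dict:
    """Serialize a group specification to plain nested dictionaries."""
    ph = spec.phenotype
    return {
        "label": spec.label,
        "n": spec.n,
        "covariates": {k: _dist_to_dict(v) for k, v in spec.covariates.items()},
        "phenotype": {
            "peak_strain_pct": ph.peak_strain_pct,
            "strain_rel_sd": ph.strain_rel_sd,
            "segment_cv": ph.segment_cv,
            "releng_frac_mean": ph.releng_frac_mean,
            "releng_frac_sd": ph.releng_frac_sd,
            "pss_prob": ph.pss_prob,
            "pss_magnitude_pct": ph.pss_magnitude_pct,
            "ivc_s": list(ph.ivc_s),
            "ejection_s": list(ph.ejection_s),
            "ivr_s": list(ph.ivr_s),
            "trace_hz": ph.trace_hz,
            "severity_effects": dict(ph.severity_effects),
        },
    }


def spec_from_dict(data: Mapping) -> GroupSpec:
    """Rebuild a group specification from :func:`spec_to_dict` output."""
    ph = dict(data["phenotype"])
    for key in ("ivc_s", "ejection_s", "ivr_s"):
        if key in ph:
            ph[key] = tuple(ph[key])
    return GroupSpec(
        label=data["label"],
        n=int(data["n"]),
        covariates={k: _dist_from_dict(v) for k, v in data["covariates"].items()},
        phenotype=PhenotypeSpec(**ph),
    )


def specs_to_yaml(path, nc_spec: GroupSpec | None = None,
                  dm_spec: GroupSpec | None = None) -> None:
    """Write both arms' specifications (defaults if omitted) to a YAML file."""
    import yaml

    payload = {
        "nc": spec_to_dict(nc_spec or nc_group_spec()),
        "t2dm": spec_to_dict(dm_spec or t2dm_group_spec()),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def specs_from_yaml(path) -> tuple[GroupSpec, GroupSpec]:
    """Load both arms' specifications from a YAML file."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return spec_from_dict(payload["nc"]), spec_from_dict(payload["t2dm"])
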