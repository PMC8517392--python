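"""End-to-end study pipeline: simulate -> compute work -> analyze -> report.

``run_full_study`` reproduces the structure of a two-group myocardial-work
study report: a demographics/clinical comparison table, a conventional
echo + strain table, a myocardial-work comparison table (folded into one
comparison table here), GLS-vs-work correlations, univariable plus
stepwise multivariable regressions of GWI and GCW in the diabetic arm,
and Bland-Altman observer-agreement tables on simulated re-measurements.
Outputs are CSV tables stamped with the seed and a configuration hash so
runs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .cohort import (
    SubjectBundle,
    generate_cohort,
    nc_group_spec,
    t2dm_group_spec,
)
from .errors import ConfigurationError
from .pressure import CuffPressure, scale_to_cycle, RAISED_COSINE_TEMPLATE
from .stats import (
    bland_altman,
    chi_square_2x2,
    mann_whitney,
    ols_standardized,
    pearson_r,
    stepwise_select,
    t_from_raw,
)
from .work import subject_work

__all__ = [
    "RunConfig",
    "run_full_study",
    "make_fixtures",
    "compute_work_table",
    "comparison_table",
    "correlation_table",
    "regression_tables",
    "agreement_table",
    "DEFAULT_ROUTING",
]

#: Which test each comparison-table variable is routed to, mirroring the
#: mean±SD (t) vs median(IQR) (Mann-Whitney Z) vs count (chi-square) layout
#: of the study tables this pipeline emulates.
DEFAULT_ROUTING: dict[str, str] = {
    "male": "chi2",
    "smoking": "chi2",
    "age_yr": "t",
    "bmi_kg_m2": "t",
    "bsa_m2": "t",
    "sbp_mmhg": "t",
    "dbp_mmhg": "t",
    "pulse_pressure_mmhg": "t",
    "heart_rate_bpm": "t",
    "tc_mmol_l": "t",
    "tg_mmol_l": "t",
    "ldl_mmol_l": "t",
    "hba1c_pct": "t",
    "hdl_mmol_l": "Z",
    "lvedv_ml": "t",
    "lvef_pct": "Z",
    "gls_pct": "Z",
    "gwi_mmhg_pct": "t",
    "gcw_mmhg_pct": "t",
    "gww_mmhg_pct": "Z",
    "gwe_pct": "Z",
}

#: Candidate predictors of myocardial work in the diabetic arm.
WORK_PREDICTORS: tuple[str, ...] = (
    "age_yr",
    "bsa_m2",
    "heart_rate_bpm",
    "sbp_mmhg",
    "dbp_mmhg",
    "pulse_pressure_mmhg",
    "tc_mmol_l",
    "tg_mmol_l",
    "hdl_mmol_l",
    "ldl_mmol_l",
    "hba1c_pct",
    "fpg_mmol_l",
    "ppg2h_mmol_l",
    "diabetes_duration_yr",
)

#: SD of the simulated re-measurement difference per work parameter,
#: (intra-observer, inter-observer), in the parameter's own units.
REPLICATE_SD: dict[str, tuple[float, float]] = {
    "gwi_mmhg_pct": (36.0, 61.0),
    "gcw_mmhg_pct": (88.0, 70.0),
    "gww_mmhg_pct": (4.2, 6.4),
    "gwe_pct": (0.51, 0.49),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``"synthetic"`` (simulate a cohort from the group specs)
    or ``"from-files"`` (load strain/events/cohort CSVs).
    """

    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "pslwork_run"
    n_nc: int = 50
    n_t2dm: int = 50
    n_grid: int = 1000
    p_enter: float = 0.05
    p_remove: float = 0.10
    n_replicate_subjects: int = 20
    strain_csv: str | None = None
    events_csv: str | None = None
    cohort_csv: str | None = None
    routing: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROUTING))

    def validate(self) -> None:
        if self.mode not in ("synthetic", "from-files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "from-files":
            for key in ("strain_csv", "events_csv", "cohort_csv"):
                if getattr(self, key) is None:
                    raise ConfigurationError(
                        f"from-files mode requires config key {key!r}"
                    )

    def hash(self) -> str:
        """Digest of the parameters that affect computed values.

        File locations (output directory, input paths) are excluded so
        the same analysis written to two places carries the same stamp.
        """
        blob = json.dumps(self.stable_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stable_dict(self) -> dict:
        """The configuration minus file locations (the hashed payload)."""
        return {
            k: v
            for k, v in asdict(self).items()
            if k not in ("outdir", "strain_csv", "events_csv", "cohort_csv")
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def compute_work_table(
    traces_by_subject: Mapping[str, list],
    events_by_subject: Mapping[str, object],
    cohort: pd.DataFrame,
    n_grid: int = 1000,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject global work indices from input traces, events and cuff.

    Subjects missing any of traces / events / cuff pressures, or with an
    incomplete 17-segment set, are excluded and returned in the exclusion
    list rather than silently dropped.
    """
    cov = cohort.set_index("subject_id")
    rows, excluded = [], []
    for sid in sorted(traces_by_subject):
        if sid not in events_by_subject or sid not in cov.index:
            excluded.append(f"{sid}: missing valve events or cohort row")
            continue
        try:
            cuff = CuffPressure(
                sbp=float(cov.loc[sid, "sbp_mmhg"]),
                dbp=float(cov.loc[sid, "dbp_mmhg"]),
            )
            events = events_by_subject[sid]
            pressure = scale_to_cycle(RAISED_COSINE_TEMPLATE, events, cuff)
            gw = subject_work(
                traces_by_subject[sid], pressure, events, n_grid=n_grid
            )
        except Exception as exc:  # surfaced per subject, run continues
            excluded.append(f"{sid}: {exc}")
            continue
        rows.append(
            {
                "subject_id": sid,
                "gls_pct": gw.gls,
                "gwi_mmhg_pct": gw.gwi,
                "gcw_mmhg_pct": gw.gcw,
                "gww_mmhg_pct": gw.gww,
                "gwe_pct": gw.gwe,
            }
        )
    return pd.DataFrame(rows), excluded


def comparison_table(
    cohort: pd.DataFrame,
    routing: Mapping[str, str] = DEFAULT_ROUTING,
    group_col: str = "group",
    reference_group: str = "NC",
) -> pd.DataFrame:
    """Two-group comparison of every routed variable present in the table.

    The reference (control) group is group 1 throughout, so signs match
    the control-first convention.  Normally distributed variables use the
    pooled t-test, skewed ones the Mann-Whitney Z, binary ones the
    Pearson chi-square (counts of ones vs zeros per group).
    """
    groups = sorted(cohort[group_col].unique(), key=lambda g: g != reference_group)
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly two groups, got {groups}")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for var, how in routing.items():
        if var not in cohort.columns:
            continue
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x2 = g2[var].dropna().to_numpy(dtype=float)
        if x1.size < 2 or x2.size < 2:
            continue
        if how == "t":
            res = t_from_raw(x1, x2)
            s1 = f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}"
            s2 = f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}"
        elif how == "Z":
            res = mann_whitney(x1, x2)
            q1 = np.percentile(x1, [25, 50, 75])
            q2 = np.percentile(x2, [25, 50, 75])
            s1 = f"{q1[1]:.2f} ({q1[2] - q1[0]:.2f})"
            s2 = f"{q2[1]:.2f} ({q2[2] - q2[0]:.2f})"
        elif how == "chi2":
            a, b = int(x1.sum()), int(x1.size - x1.sum())
            c, d = int(x2.sum()), int(x2.size - x2.sum())
            res = chi_square_2x2(a, b, c, d)
            s1, s2 = f"{a} ({100 * a / x1.size:.0f}%)", f"{c} ({100 * c / x2.size:.0f}%)"
        else:
            raise ConfigurationError(f"unknown routing {how!r} for {var!r}")
        rows.append(
            {
                "variable": var,
                f"{groups[0]}_summary": s1,
                f"{groups[1]}_summary": s2,
                "test": res.statistic_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of GLS against each global work parameter."""
    rows = []
    for var in ("gwi_mmhg_pct", "gcw_mmhg_pct", "gww_mmhg_pct", "gwe_pct"):
        if var not in cohort.columns:
            continue
        sub = cohort[["gls_pct", var]].dropna()
        r, p = pearson_r(sub["gls_pct"], sub[var])
        rows.append({"pair": f"gls_pct vs {var}", "r": r, "p_value": p})
    return pd.DataFrame(rows)


def regression_tables(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = WORK_PREDICTORS,
    group: str = "T2DM",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> pd.DataFrame:
    """Univariable screen plus stepwise multivariable model of one outcome.

    Each candidate is first fitted alone (standardized beta and p);
    candidates with univariable p < 0.05 are passed to bidirectional
    stepwise selection.  The returned table carries both the univariable
    and the multivariable columns, with the model R-squared and adjusted
    R-squared attached to the frame's ``attrs``.

    Diabetes duration is strongly right-skewed, so it enters the models
    as ``log(1 + duration)`` (reported under its own name).
    """
    sub = cohort[cohort["group"] == group] if "group" in cohort.columns else cohort
    present = [p for p in predictors if p in sub.columns and sub[p].notna().all()]
    y = sub[outcome].to_numpy(dtype=float)

    def column(name: str) -> np.ndarray:
        x = sub[name].to_numpy(dtype=float)
        return np.log1p(x) if name == "diabetes_duration_yr" else x

    uni = {}
    for name in present:
        res = ols_standardized(y, column(name), names=[name])
        uni[name] = (res.beta[name], res.p_values[name])
    candidates = [n for n in present if uni[n][1] < 0.05]
    if candidates:
        multi = stepwise_select(
            y,
            np.column_stack([column(n) for n in candidates]),
            names=candidates,
            p_enter=p_enter,
            p_remove=p_remove,
        )
    else:
        multi = None
    rows = []
    for name in present:
        b, p = uni[name]
        in_model = multi is not None and not multi.empty and name in multi.beta
        rows.append(
            {
                "predictor": name,
                "uni_beta": b,
                "uni_p": p,
                "multi_beta": multi.beta[name] if in_model else np.nan,
                "multi_p": multi.p_values[name] if in_model else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["outcome"] = outcome
    table.attrs["r_squared"] = multi.r_squared if multi and not multi.empty else 0.0
    table.attrs["adj_r_squared"] = (
        multi.adj_r_squared if multi and not multi.empty else 0.0
    )
    table.attrs["selected"] = list(multi.predictors) if multi else []
    return table


def agreement_table(
    cohort: pd.DataFrame,
    seed: int,
    n_subjects: int = 20,
    replicate_sd: Mapping[str, tuple[float, float]] = REPLICATE_SD,
) -> pd.DataFrame:
    """Bland-Altman observer agreement on simulated re-measurements.

    Re-measurement is emulated as additive Gaussian noise on the computed
    work parameters of ``n_subjects`` randomly chosen subjects, with
    separate intra- and inter-observer difference SDs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    have = cohort.dropna(subset=list(replicate_sd))
    n_subjects = min(n_subjects, len(have))
    pick = have.iloc[
        np.sort(rng.choice(len(have), size=n_subjects, replace=False))
    ]
    rows = []
    for which, idx in (("intraobserver", 0), ("interobserver", 1)):
        for var, sds in replicate_sd.items():
            m1 = pick[var].to_numpy(dtype=float)
            m2 = m1 + rng.normal(0.0, sds[idx], size=m1.size)
            res = bland_altman(m1, m2)
            rows.append(
                {
                    "comparison": which,
                    "parameter": var,
                    "mean_1": m1.mean(),
                    "mean_2": m2.mean(),
                    "bias": res.bias,
                    "loa_low": res.loa_low,
                    "loa_high": res.loa_high,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def run_full_study(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline and write the report bundle to ``config.outdir``.

    Returns a mapping from table name to the written file path.  The run
    log records the seed, the configuration hash, library versions and
    any per-subject exclusions; every output carries the same stamp in
    its ``#`` metadata header, so two runs with one seed are
    byte-identical.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.hash()}
    log_lines = [f"{k}: {v}" for k, v in meta.items()]
    import pslwork

    log_lines.append(f"pslwork_version: {pslwork.__version__}")
    log_lines.append(f"numpy_version: {np.__version__}")
    log_lines.append(f"config: {json.dumps(config.stable_dict(), sort_keys=True)}")

    excluded: list[str] = []
    if config.mode == "synthetic":
        cohort, bundles = generate_cohort(
            nc_group_spec(config.n_nc),
            t2dm_group_spec(config.n_t2dm),
            seed=config.seed,
            n_grid=config.n_grid,
        )
        traces = {sid: b.traces for sid, b in bundles.items()}
        events = {sid: b.events for sid, b in bundles.items()}
        pio.write_table(pio.traces_to_frame(traces), outdir / "strain_traces.csv", meta)
        pio.write_table(pio.events_to_frame(events), outdir / "valve_events.csv", meta)
        n_input = len(cohort)
    else:
        traces = pio.frame_to_traces(pio.read_table(config.strain_csv))
        events = pio.frame_to_events(pio.read_table(config.events_csv))
        covariates = pio.read_table(config.cohort_csv)
        n_input = len(traces)
        work, excluded = compute_work_table(
            traces, events, covariates, n_grid=config.n_grid
        )
        cohort = covariates.merge(work, on="subject_id", how="inner")

    outputs: dict[str, Path] = {}
    outputs["cohort"] = pio.write_table(cohort, outdir / "cohort.csv", meta)
    work_cols = ["subject_id", "gls_pct", "gwi_mmhg_pct", "gcw_mmhg_pct",
                 "gww_mmhg_pct", "gwe_pct"]
    outputs["work"] = pio.write_table(
        cohort[work_cols], outdir / "work_table.csv", meta
    )
    if cohort["group"].nunique() == 2:
        outputs["comparison"] = pio.write_table(
            comparison_table(cohort, config.routing), outdir / "comparison_table.csv",
            meta,
        )
    outputs["correlation"] = pio.write_table(
        correlation_table(cohort), outdir / "correlation_table.csv", meta
    )
    dm = cohort[cohort["group"] == "T2DM"]
    if len(dm) > len(WORK_PREDICTORS) + 2:
        for outcome, name in (("gwi_mmhg_pct", "regression_gwi"),
                              ("gcw_mmhg_pct", "regression_gcw")):
            table = regression_tables(
                cohort, outcome, p_enter=config.p_enter, p_remove=config.p_remove
            )
            log_lines.append(
                f"{name}: selected={table.attrs['selected']} "
                f"R2={table.attrs['r_squared']:.4f} "
                f"adjR2={table.attrs['adj_r_squared']:.4f}"
            )
            outputs[name] = pio.write_table(table, outdir / f"{name}.csv", meta)
    else:
        log_lines.append("regression skipped: diabetic arm too small")
    if len(cohort.dropna(subset=["gwi_mmhg_pct"])) >= 2:
        outputs["agreement"] = pio.write_table(
            agreement_table(cohort, config.seed, config.n_replicate_subjects),
            outdir / "agreement_table.csv",
            meta,
        )

    log_lines.append(f"subjects_in: {n_input}")
    log_lines.append(f"subjects_out: {len(cohort)}")
    log_lines.append(f"excluded: {len(excluded)}")
    log_lines.extend(f"excluded_subject: {line}" for line in excluded)
    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    outputs["log"] = log_path
    return outputs


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a self-contained 4-subject (2 NC, 2 T2DM) CSV fixture trio."""
    outdir = Path(outdir)
    cohort, bundles = generate_cohort(
        nc_group_spec(2), t2dm_group_spec(2), seed=seed, n_grid=600
    )
    traces = {sid: b.traces for sid, b in bundles.items()}
    events = {sid: b.events for sid, b in bundles.items()}
    meta = {"seed": seed, "fixture": "4-subject demo cohort"}
    cov_cols = [c for c in cohort.columns if not c.startswith(("gls", "gwi", "gcw",
                                                              "gww", "gwe"))]
    return {
        "strain": pio.write_table(
            pio.traces_to_frame(traces), outdir / "strain_traces.csv", meta
        ),
        "events": pio.write_table(
            pio.events_to_frame(events), outdir / "valve_events.csv", meta
        ),
        "cohort": pio.write_table(cohort[cov_cols], outdir / "cohort.csv", meta),
    }
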