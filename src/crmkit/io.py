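"""File I/O: trial-history CSV, design configuration, and trial reports.

History CSV schema (header mandatory, comma-separated, UTF-8):
``patient_id,cohort,dose_level,dlt`` with 1-based integer dose levels and
0/1 DLT flags.  Design configurations round-trip through a flat YAML (or
JSON) mapping of the :class:`~crmkit.design.DesignSpec` fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .design import DesignSpec, PatientRecord, ToxicityHistory, ValidationError
from .model import (
    dose_toxicity,
    posterior_beta_quantile,
    posterior_summary,
    scale_doses,
)

__all__ = [
    "load_history",
    "save_history",
    "design_to_dict",
    "design_from_dict",
    "load_design",
    "save_design",
    "trial_report",
    "write_report",
]

HISTORY_COLUMNS = ("patient_id", "cohort", "dose_level", "dlt")

REPORT_COLUMNS = (
    "dose_level",
    "dose_mg",
    "n_treated",
    "n_dlt",
    "prop_dlt",
    "posterior_dlt_prob",
    "ci90_lower",
    "ci90_upper",
)


def load_history(path, n_levels: int | None = None) -> ToxicityHistory:
    """Read and validate a trial-history CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ValidationError(f"cannot parse history CSV {path}: {exc}") from exc
    missing = [c for c in HISTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"history CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            cohort = int(row["cohort"])
            level = int(row["dose_level"])
            dlt = int(row["dlt"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"history CSV row {i}: malformed values") from exc
        records.append(PatientRecord(str(row["patient_id"]), cohort, level, dlt))
    hist = ToxicityHistory(records)
    hist.validate(n_levels=n_levels)
    return hist


def save_history(history: ToxicityHistory, path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in history.records])[
        list(HISTORY_COLUMNS)
    ].to_csv(path, index=False)


def design_to_dict(spec: DesignSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["doses_mg"] = list(spec.doses_mg)
    d["skeleton"] = list(spec.skeleton)
    return d


def design_from_dict(d: dict) -> DesignSpec:
    fields = {f.name for f in dataclasses.fields(DesignSpec)}
    unknown = set(d) - fields
    if unknown:
        raise ValidationError(f"unknown design fields: {sorted(unknown)}")
    return DesignSpec(**d)


def load_design(path) -> DesignSpec:
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML superset also parses JSON
    if not isinstance(data, dict):
        raise ValidationError(f"design config {path} must be a mapping")
    return design_from_dict(data)


def save_design(spec: DesignSpec, path) -> None:
    path = Path(path)
    d = design_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def trial_report(history: ToxicityHistory, spec: DesignSpec) -> tuple[pd.DataFrame, dict]:
    """Per-level DLT summary with posterior estimates and 90% intervals.

    The 90% interval of each level's DLT probability is the equal-tailed
    posterior interval of theta(x_k, beta) induced by the posterior of
    beta: since toxicity is decreasing in beta, it is
    [theta(x_k, q95(beta)), theta(x_k, q05(beta))].  Also returns the
    rule-1 posterior probability and the posterior slope mean.
    """
    summ = posterior_summary(history, spec)
    counts = history.counts_by_level(spec.n_levels)
    q05 = posterior_beta_quantile(history, spec, 0.05)
    q95 = posterior_beta_quantile(history, spec, 0.95)
    xs = scale_doses(spec.skeleton, spec.intercept)
    rows = []
    for k in range(spec.n_levels):
        n, t = counts[k]
        rows.append(
            {
                "dose_level": k + 1,
                "dose_mg": spec.doses_mg[k],
                "n_treated": n,
                "n_dlt": t,
                "prop_dlt": t / n if n else float("nan"),
                "posterior_dlt_prob": summ.tox_hat[k],
                "ci90_lower": float(dose_toxicity(xs[k], q95, spec.intercept)),
                "ci90_upper": float(dose_toxicity(xs[k], q05, spec.intercept)),
            }
        )
    meta = {
        "n_patients": history.n_patients,
        "beta_mean": summ.beta_mean,
        "prob_lowest_toxic": summ.prob_lowest_toxic,
        "theta_L": spec.theta_L_effective,
        "target_theta": spec.target_theta,
    }
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS)), meta


def write_report(
    history: ToxicityHistory,
    spec: DesignSpec,
    path,
    fmt: str = "csv",
) -> pd.DataFrame:
    """Write the per-level report table (CSV or JSON) and return it."""
    table, meta = trial_report(history, spec)
    path = Path(path)
    if fmt == "csv":
        table.to_csv(path, index=False)
        meta_path = path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(meta, indent=2))
    elif fmt == "json":
        path.write_text(
            json.dumps({"levels": table.to_dict(orient="records"), **meta}, indent=2)
        )
    else:
        raise ValidationError(f"unsupported report format: {fmt}")
    return table
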