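"""Cohort CSV reading, YAML configuration and run artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import DomainError

__all__ = ["CohortParseError", "read_cohort", "load_config", "write_summary",
           "write_draws", "write_run_report", "DEFAULT_CONFIG"]

#: estimator defaults mirrored as a config mapping (see docs/methods.md)
DEFAULT_CONFIG: dict = {
    "validity1": (0.3, 0.7),
    "validity2": (0.4, 0.7),
    "ci_level": 0.90,
    "error_corr": "admissible",
    "error_corr_value": 0.0,
    "n_samples": 50_000,
    "burn_in": 5_000,
    "tuning": 5_000,
    "prior_sd_beta": 1_000.0,
    "iw_df": 2.0,
}

_COLUMNS = ("time", "event", "q1", "q2")


class CohortParseError(ValueError):
    """A cohort CSV failed validation; the message cites the offending rows."""


def read_cohort(path, columns: dict | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Expects header columns time, event, q1, q2; ``columns`` remaps them, e.g.
    ``{"time": "followup_years"}``. Row numbers in error messages are 1-based
    data rows (header excluded).
    """
    df = pd.read_csv(path)
    mapping = {v: k for k, v in (columns or {}).items()}
    df = df.rename(columns=mapping)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing columns: {', '.join(missing)}")
    df = df[list(_COLUMNS)]
    for col in _COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()] + 1
        if len(bad):
            raise CohortParseError(
                f"non-numeric or missing '{col}' on row(s) {list(bad[:10])}")
        df[col] = numeric
    bad = df.index[~df["event"].isin((0, 1))] + 1
    if len(bad):
        raise CohortParseError(f"event values outside {{0, 1}} on row(s) "
                               f"{list(bad[:10])}")
    bad = df.index[df["time"] <= 0] + 1
    if len(bad):
        raise CohortParseError(f"non-positive time on row(s) {list(bad[:10])}")
    return df


def load_config(path=None) -> dict:
    """Load a YAML config and merge it over the defaults.

    Recognised keys are the :class:`~mesens.engine.MeasurementErrorCoxAdjuster`
    parameters; ``validity1``/``validity2`` may be mappings with
    ``lower``/``upper`` (and optional ``ci``) or two-element lists;
    ``error_correlation`` may be a mapping with ``mode`` and ``value``.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise DomainError("config file must contain a mapping")
    for key in ("validity1", "validity2"):
        if key in user and isinstance(user[key], dict):
            spec = user[key]
            val = (float(spec["lower"]), float(spec["upper"]))
            if "ci" in spec:
                val = val + (float(spec["ci"]),)
            user[key] = val
        elif key in user and isinstance(user[key], list):
            user[key] = tuple(float(v) for v in user[key])
    if "error_correlation" in user:
        spec = user.pop("error_correlation")
        user["error_corr"] = spec.get("mode", "admissible")
        if "value" in spec:
            user["error_corr_value"] = float(spec["value"])
    unknown = set(user) - set(DEFAULT_CONFIG) - {"random_state"}
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _provenance_lines(config: dict, seed) -> list[str]:
    resolved = {**config, "seed": seed}
    return [f"# {json.dumps(resolved, default=str, sort_keys=True)}"]


def write_summary(summary: pd.DataFrame, outdir, config: dict, seed) -> None:
    """Write the summary table as CSV and JSON with a provenance header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "summary.csv"
    with open(csv_path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config, seed)) + "\n")
        summary.to_csv(fh, float_format="%.6g")
    flat = {f"{m}.{c}": row.to_dict()
            for (m, c), row in summary.round(6).iterrows()}
    payload = {"config": {k: str(v) for k, v in config.items()},
               "seed": seed, "summary": flat}
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2))


def write_draws(draws: dict, outdir) -> None:
    """Write retained aligned draws to a columnar CSV with iteration index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame({
        "beta_t1_multivariate": draws["beta_multivariate"][:, 0],
        "beta_t2_multivariate": draws["beta_multivariate"][:, 1],
        "beta_t1_univariate": draws["beta_univariate"][:, 0],
        "beta_t2_univariate": draws["beta_univariate"][:, 1],
        "beta_q1_unadjusted": draws["beta_unadjusted"][:, 0],
        "beta_q2_unadjusted": draws["beta_unadjusted"][:, 1],
        "rho1": draws["rho1"], "rho2": draws["rho2"],
        "rho_eps": draws["rho_eps"], "rho_t": draws["rho_t"],
    })
    table.index.name = "iteration"
    table.to_csv(outdir / "draws.csv", float_format="%.8g")


def write_run_report(outdir, config: dict, seed, diagnostics: dict,
                     n_subjects: int, n_events: int) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["measurement-error adjustment run report",
             f"seed: {seed}",
             f"subjects: {n_subjects}  events: {n_events}",
             "configuration:"]
    lines += [f"  {k}: {v}" for k, v in sorted(config.items())]
    lines.append("diagnostics:")
    lines += [f"  {k}: {np.round(v, 6)}" for k, v in diagnostics.items()]
    (outdir / "run_report.txt").write_text("\n".join(lines) + "\n")
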