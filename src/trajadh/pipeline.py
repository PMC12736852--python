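"""Reproducible end-to-end runner: schema-validated CSV/JSON IO, stage
orchestration (simulate -> adherence -> fit -> diagnose -> report ->
outcomes), and a manifest recording files, hashes, seeds, and versions.

Artifacts are plain CSV and JSON; dates are integer day offsets from
baseline.  Every numeric output is reproducible byte-for-byte given the
same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import adherence as adh
from . import gbtm, model_selection, outcomes, predictor_report, synthetic_data

SCHEMA_VERSION = "trajadh-1"

# column -> (dtype kind, min, max); None bound = unbounded
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, float | None, float | None]]] = {
    "daily_activity": {
        "subject_id": ("any", None, None),
        "day": ("i", 1, None),
        "steps": ("i", 0, None),
        "fairly_active_min": ("f", 0, 1440),
        "very_active_min": ("f", 0, 1440),
    },
    "weekly_adherence": {
        "subject_id": ("any", None, None),
        "week": ("i", 1, None),
        "n_wear_days": ("i", 0, 7),
        "weekly_mvpa_min": ("f", 0, None),
        "adherence_pct": ("f", 0, None),
        "is_valid": ("b", None, None),
    },
    "covariates": {
        "subject_id": ("any", None, None),
        "age": ("f", 0, None),
        "female": ("i", 0, 1),
        "partnered": ("i", 0, 1),
        "covid_era": ("i", 0, 1),
        "arm": ("i", 0, 1),
        "first_week_mvpa": ("f", 0, None),
    },
    "weights": {
        "subject_id": ("any", None, None),
        "visit": ("any", None, None),
        "weight_kg": ("f", 0, None),
        "source": ("any", None, None),
        "date_offset_days": ("f", None, None),
    },
}


class SchemaError(ValueError):
    pass


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Unknown extra columns are kept but noted; a missing column, an
    uncoercible type, or an out-of-range value raises :class:`SchemaError`
    naming the column and the first offending row.
    """
    if schema not in TABLE_SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    return validate_table(df, schema)


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing columns {missing}")
    for col, (kind, lo, hi) in cols.items():
        s = df[col]
        if kind in ("i", "f"):
            vals = pd.to_numeric(s, errors="coerce")
            bad = vals.isna() & s.notna()
            if bad.any():
                raise SchemaError(
                    f"schema {schema!r}: column {col!r} non-numeric at row "
                    f"{int(bad.idxmax())}"
                )
            for bound, op, word in ((lo, np.less, "below"), (hi, np.greater, "above")):
                if bound is not None:
                    viol = op(vals, bound) & vals.notna()
                    if viol.any():
                        raise SchemaError(
                            f"schema {schema!r}: column {col!r} {word} bound "
                            f"{bound} at row {int(viol.idxmax())}"
                        )
        if kind == "b":
            try:
                df[col] = s.astype(bool)
            except (ValueError, TypeError) as exc:
                raise SchemaError(
                    f"schema {schema!r}: column {col!r} not boolean"
                ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    if schema is not None:
        validate_table(df, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    out_dir: str = "trajadh_out"
    seed: int = 0
    n_subjects: int = 502
    simulate: bool = True
    daily_path: str | None = None
    covariates_path: str | None = None
    weights_path: str | None = None
    n_groups: int = 4
    polynomial_orders: tuple[int, ...] = (0, 3, 3, 2)
    membership_covariates: tuple[str, ...] = ()
    n_starts: int = 3
    pi_ci_boot: int = 0
    run_selection_scan: bool = False
    k_max: int = 5
    log_level: str = "info"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write a manifest.

    A stage failure raises with the failing stage named; outputs written up
    to that point are renamed with a ``.partial`` suffix so a half-finished
    run is never mistaken for a complete one.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # ---------------------------------------------------------- simulate
        stage = "simulate"
        if config.simulate:
            cc = synthetic_data.published_model_config(
                n_subjects=config.n_subjects, seed=config.seed
            )
            cohort = synthetic_data.generate_cohort(cc)
            daily = cohort.daily
            covariates = cohort.covariates
            weights = cohort.weights
            for name, df in (
                ("daily_activity", daily),
                ("covariates", covariates),
                ("weights", weights),
            ):
                written.append(write_table(df, out / f"{name}.csv"))
            written.append(
                write_table(
                    pd.DataFrame(
                        {
                            "subject_id": covariates["subject_id"],
                            "true_group": cohort.true_group.to_numpy(),
                        }
                    ),
                    out / "truth.csv",
                )
            )
        else:
            for name, p in (
                ("daily", config.daily_path),
                ("covariates", config.covariates_path),
                ("weights", config.weights_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"stage needs --{name} input: {p!r}")
            daily = read_table(config.daily_path, "daily_activity")
            covariates = read_table(config.covariates_path, "covariates")
            weights = read_table(config.weights_path, "weights")

        # --------------------------------------------------------- adherence
        stage = "adherence"
        weekly = adh.summarize_weeks(daily)
        written.append(write_table(weekly, out / "weekly_adherence.csv"))

        # --------------------------------------------------------- selection
        stage = "selection"
        if config.run_selection_scan:
            scan = model_selection.scan_groups(
                weekly, covariates, k_max=config.k_max, seed=config.seed,
                n_starts=config.n_starts,
            )
            sel = {
                "recommended_K": scan.attrs.get("recommended_K"),
                "table": scan.to_dict(orient="records"),
            }
            p = out / "selection_report.json"
            p.write_text(json.dumps(sel, indent=2, default=float))
            written.append(p)

        # --------------------------------------------------------------- fit
        stage = "fit"
        spec = gbtm.GbtmSpec(
            config.n_groups,
            tuple(config.polynomial_orders),
            membership_covariates=tuple(config.membership_covariates),
        )
        fit = gbtm.fit(
            spec, weekly, covariates, n_starts=config.n_starts, seed=config.seed
        )
        report = fit.to_dict()
        report["schema_version"] = SCHEMA_VERSION
        report["seed"] = config.seed
        idx = model_selection.indices_for_fit(fit)
        report["fit_indices"] = {
            "bic_obs": idx.bic_obs, "bic_subj": idx.bic_subj, "aic": idx.aic,
        }
        p = out / "fit_report.json"
        p.write_text(json.dumps(report, indent=2))
        written.append(p)

        stage = "diagnose"
        post = gbtm.posteriors(fit, weekly, covariates)
        written.append(write_table(post, out / "posteriors.csv"))
        diag = model_selection.adequacy(
            post, fit, pi_ci_boot=config.pi_ci_boot, seed=config.seed,
            weekly=weekly, covariates=covariates,
        )
        p = out / "diagnostics.json"
        p.write_text(json.dumps(diag.to_dict(), indent=2))
        written.append(p)

        # ------------------------------------------------------------ report
        stage = "report"
        if fit.spec.membership_covariates:
            rows = predictor_report.build_rows(fit)
            written.append(write_table(rows, out / "predictors.csv"))

        # ---------------------------------------------------------- outcomes
        stage = "outcomes"
        results = {}
        for pop in ("full", "completers"):
            res = outcomes.outcome_analysis(weights, post, population=pop)
            results[pop] = res.to_dict()
        p = out / "outcomes.json"
        p.write_text(json.dumps(results, indent=2, default=float))
        written.append(p)

    except Exception as exc:
        for f in written:
            if f.exists():
                f.rename(f.with_suffix(f.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    stage = "manifest"
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {f.name: _sha256(f) for f in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
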