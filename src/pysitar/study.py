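"""End-to-end study driver: fit every configured outcome, derive the
timing table, variance-explained table and tempo correlation matrix,
and write the bundle to disk.

The per-outcome analysis conventions default to the study's: spline
df 5 with no transform for height; df 3 with sqrt for IGF-1 and log
for testosterone/oestradiol; the logistic stage model for Tanner
measures.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data import LongSeries, StageSeries, ValidationError
from .metrics import (
    BoundaryPeakWarning,
    age_at_peak_velocity,
    bootstrap_apv_se,
    individual_timings,
)
from .model import SitarModel, SitarSpec
from .serialize import fit_to_json, stage_fit_to_json
from .stages import StageModel
from .tempo import collect_tempo_table, tempo_correlations

__all__ = ["AnalysisConfig", "StudyBundle", "run_study", "DEFAULT_OUTCOME_SPECS"]

logger = logging.getLogger("pysitar")

DEFAULT_OUTCOME_SPECS: dict[str, SitarSpec] = {
    "height": SitarSpec(df=5, transform="identity"),
    "igf1": SitarSpec(df=3, transform="sqrt"),
    "testosterone": SitarSpec(df=3, transform="log"),
    "oestradiol": SitarSpec(df=3, transform="log"),
}


@dataclass
class AnalysisConfig:
    """Configuration of a full study run."""

    long_csv: str | Path | None = None
    stage_csv: str | Path | None = None
    sex: str | None = None
    outcome_specs: dict[str, SitarSpec] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SPECS)
    )
    seed: int = 20150108
    n_boot: int = 0  # 0 = skip bootstrap SEs
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        for path in (self.long_csv, self.stage_csv):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")


@dataclass
class StudyBundle:
    """Everything a study run produces."""

    fits: dict
    stage_fits: dict
    timing_table: pd.DataFrame
    variance_table: pd.DataFrame
    tempo_report: object | None
    failures: dict[str, str]
    excluded: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.failures


def read_long_csv(path, age_window=(8.0, 16.5)) -> LongSeries:
    """Read and validate a long-format measurement CSV
    (``subject_id,sex,age,outcome,value``)."""
    return LongSeries(pd.read_csv(path), age_window)


def read_stage_csv(path, age_window=(8.0, 16.5)) -> StageSeries:
    """Read and validate a Tanner-stage CSV
    (``subject_id,sex,age,measure,stage``)."""
    return StageSeries(pd.read_csv(path), age_window)


def run_study(config: AnalysisConfig,
              long_data: LongSeries | None = None,
              stage_data: StageSeries | None = None) -> StudyBundle:
    """Run the full multi-outcome analysis.

    Data may be passed directly or read from the configured CSVs.
    Each configured outcome present in the data is fitted; fit JSONs,
    the APV timing table (mean (SE), SD, N/n), the variance-explained
    table and the tempo correlation matrix are assembled, and written
    to ``config.out_dir`` when set.  Failures are collected per
    outcome rather than aborting the bundle.
    """
    import warnings

    if long_data is None and config.long_csv is not None:
        long_data = read_long_csv(config.long_csv)
    if stage_data is None and config.stage_csv is not None:
        stage_data = read_stage_csv(config.stage_csv)

    fits, stage_fits, failures, excluded = {}, {}, {}, {}
    timing_rows, var_rows = [], []

    if long_data is not None:
        if config.sex is not None:
            long_data = long_data.select(sex=config.sex)
        for outcome in long_data.outcomes:
            spec = config.outcome_specs.get(outcome)
            if spec is None:
                logger.warning("no spec configured for outcome %r; skipped",
                               outcome)
                continue
            t0 = time.monotonic()
            try:
                model = SitarModel(long_data.select(outcome=outcome), spec)
                fit = model.fit()
                fits[outcome] = fit
                excluded[outcome] = fit.n_excluded
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", BoundaryPeakWarning)
                    apv, pv = age_at_peak_velocity(fit)
                    ts = individual_timings(fit, apv)
                se = None
                if config.n_boot:
                    se = bootstrap_apv_se(model.data, spec,
                                          n_boot=config.n_boot,
                                          seed=config.seed, start=fit)
                timing_rows.append({
                    "outcome": outcome, "apv_mean": apv, "apv_se": se,
                    "apv_sd": ts.apv_sd, "peak_velocity": pv,
                    "N": fit.n_subjects, "n": fit.n_obs,
                })
                var_rows.append({
                    "outcome": outcome,
                    "resid_sd": fit.sigma,
                    "crosssectional_sd": fit.cross_sd,
                    "variance_explained": fit.variance_explained(),
                })
                if not fit.converged:
                    failures[outcome] = "did not converge"
            except Exception as exc:  # collected into the failure manifest
                failures[outcome] = f"{type(exc).__name__}: {exc}"
            logger.info("outcome %r done in %.1f s", outcome,
                        time.monotonic() - t0)

    if stage_data is not None:
        if config.sex is not None:
            stage_data = stage_data.select(sex=config.sex)
        for measure in stage_data.measures:
            name = f"stage_{measure}"
            try:
                sfit = StageModel(stage_data.select(measure=measure)).fit()
                stage_fits[name] = sfit
                timing_rows.append({
                    "outcome": name, "apv_mean": sfit.midpoint_age,
                    "apv_se": None,
                    "apv_sd": float(sfit.ranef["tempo"].std(ddof=1)),
                    "peak_velocity": sfit.rate,
                    "N": sfit.n_subjects, "n": sfit.n_obs,
                })
                var_rows.append({
                    "outcome": name, "resid_sd": sfit.sigma,
                    "crosssectional_sd": sfit.cross_sd,
                    "variance_explained": sfit.variance_explained(),
                })
                if not sfit.converged:
                    failures[name] = "did not converge"
            except Exception as exc:
                failures[name] = f"{type(exc).__name__}: {exc}"

    tempo_report = None
    all_fits = {**fits, **stage_fits}
    with_tempo = {k: f for k, f in all_fits.items()
                  if "tempo" in f.ranef.columns}
    if len(with_tempo) >= 2:
        try:
            tempo_report = tempo_correlations(collect_tempo_table(with_tempo))
        except ValueError as exc:
            logger.warning("tempo correlations unavailable: %s", exc)
    else:
        logger.warning("fewer than 2 tempo fits; no correlation report")

    bundle = StudyBundle(
        fits=fits,
        stage_fits=stage_fits,
        timing_table=pd.DataFrame(timing_rows),
        variance_table=pd.DataFrame(var_rows),
        tempo_report=tempo_report,
        failures=failures,
        excluded=excluded,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: StudyBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for outcome, fit in bundle.fits.items():
        fit_to_json(fit, out_dir / f"fit_{outcome}.json")
    for name, sfit in bundle.stage_fits.items():
        stage_fit_to_json(sfit, out_dir / f"fit_{name}.json")
    bundle.timing_table.to_csv(out_dir / "timing_table.csv", index=False)
    bundle.variance_table.to_csv(out_dir / "variance_explained.csv", index=False)
    if bundle.tempo_report is not None:
        bundle.tempo_report.pairs.to_csv(out_dir / "tempo_correlations.csv",
                                         index=False)
    manifest = {"failures": bundle.failures, "excluded": bundle.excluded}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
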