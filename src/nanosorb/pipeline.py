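"""End-to-end analysis: trace CSVs + manifest -> rate-constant report.

Stages: per-trace initial rates -> per-size normalized rates k' ->
k'-vs-reactive-area slope -> bottom-up k1, per-size top-down k2
(model and, where a plateau is observable, experimental v), k2cor and
the ratio diagnostics.  Machine output is a JSON report holding full
precision plus a per-size CSV table of the same values.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ModelConstants, cm_to_nm, nm_to_cm
from . import geometry, rate_constants
from .rates import (
    DEFAULT_RATE_WINDOW,
    AdsorptionTrace,
    fit_kprime_vs_area,
    initial_rate,
    normalized_rate,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

MANIFEST_COLUMNS = ["trace_file", "radius_nm", "conc_mmol_per_dm3", "replicate_id"]
TRACE_COLUMNS = ["time_s", "peak2_uA"]


class ManifestError(ValueError):
    """Manifest or trace file fails schema validation."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    ``peak_measurement_error`` (uA) enters the error propagation of the
    experimental-v k2 values; it defaults to zero, i.e. k'-only
    propagation.
    """

    manifest_path: Path
    output_dir: Path
    constants: ModelConstants = DEFAULT_CONSTANTS
    rate_window: tuple[float, float] = DEFAULT_RATE_WINDOW
    weighted_area_fit: bool = False
    peak_measurement_error: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        lo, hi = self.rate_window
        if not lo < hi:
            raise ValueError("rate window start must precede end")
        if self.peak_measurement_error < 0:
            raise ValueError("peak measurement error must be nonnegative")


def load_manifest(manifest_path: str | Path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s) {missing}")
    if manifest.empty:
        raise ManifestError("manifest contains no rows")
    return manifest


def load_traces(manifest: pd.DataFrame, base_dir: str | Path) -> list[AdsorptionTrace]:
    """Read every trace the manifest names; radii converted nm -> cm here."""
    base_dir = Path(base_dir)
    traces = []
    for idx, row in manifest.iterrows():
        path = base_dir / str(row["trace_file"])
        if not path.exists():
            raise ManifestError(f"manifest row {idx}: trace file not found: {path}")
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest row {idx}: {path} missing column(s) {missing}")
        try:
            trace = AdsorptionTrace(
                times=df["time_s"].to_numpy(float),
                peak_heights=df["peak2_uA"].to_numpy(float),
                concentration_Cnp=float(row["conc_mmol_per_dm3"]),
                radius_R=nm_to_cm(float(row["radius_nm"])),
                replicate_id=str(row["replicate_id"]),
            )
        except ValueError as exc:
            raise ManifestError(f"manifest row {idx}: {exc}") from exc
        traces.append(trace)
    return traces


def _experimental_max_depression(traces: list[AdsorptionTrace], const: ModelConstants):
    """Observed plateau depression for one size, or None if not reached.

    Uses the trace whose late-time tail is deepest: depression =
    initial height minus the mean of the last tenth of samples.  The
    plateau is considered observable only when the tail has flattened
    (tail slope small against the overall drop).
    """
    best = None
    for trace in traces:
        if trace.concentration_Cnp <= 0 or trace.times.size < 10:
            continue
        n_tail = max(trace.times.size // 10, 3)
        tail = trace.peak_heights[-n_tail:]
        depression = float(trace.peak_heights[0] - tail.mean())
        if depression <= 0:
            continue
        tail_drop = float(trace.peak_heights[-2 * n_tail : -n_tail].mean() - tail.mean())
        if abs(tail_drop) > 0.05 * depression:
            continue  # still decaying: plateau not reached
        depression = min(depression, const.full_suppression_current)
        if best is None or depression > best:
            best = depression
    return best


def analyze_traces(
    traces: list[AdsorptionTrace],
    config: RunConfig,
) -> dict:
    """Run the full analysis chain on in-memory traces; returns the report."""
    const = config.constants
    by_radius: dict[float, list[AdsorptionTrace]] = {}
    for trace in traces:
        by_radius.setdefault(trace.radius_R, []).append(trace)

    kprime_by_radius = {}
    for R in sorted(by_radius):
        group = by_radius[R]
        pairs = []
        for trace in group:
            rate = initial_rate(trace, config.rate_window)
            pairs.append((trace.concentration_Cnp, rate.V))
        nr = normalized_rate(pairs, R)
        kprime_by_radius[R] = nr
        logger.info(
            "size %.3g nm: %d traces, k' = %.4g +/- %.2g (r^2 = %.4f)",
            cm_to_nm(R), len(group), nr.k_prime, nr.k_prime_sd, nr.r_squared,
        )

    radii = sorted(kprime_by_radius)
    series = [
        (geometry.reactive_area_per_mmol(R, const),
         kprime_by_radius[R].k_prime,
         kprime_by_radius[R].k_prime_sd)
        for R in radii
    ]
    slope_fit = fit_kprime_vs_area(series, weighted=config.weighted_area_fit)
    logger.info(
        "k' vs A: slope = %.4g +/- %.2g, r^2 = %.6f",
        slope_fit.slope, slope_fit.slope_sd, slope_fit.r_squared,
    )

    k1 = rate_constants.k1_bottom_up(slope_fit.slope, slope_fit.slope_sd, const)
    k2cor = rate_constants.k2cor_table(slope_fit.slope, radii, const)

    k2_model_vals = []
    per_size = []
    for R, k2c in zip(radii, k2cor.values):
        nr = kprime_by_radius[R]
        geo = geometry.reactive_area_result(R, const)
        v_model = geo.v_model
        k2_model = rate_constants.k2_top_down(
            max(nr.k_prime, 0.0), R, v_model, const, k_prime_sd=nr.k_prime_sd
        )
        k2_model_vals.append(k2_model.value)

        exp_depression = _experimental_max_depression(by_radius[R], const)
        if exp_depression is not None:
            v_exp = geometry.v_factor(R, const, max_depression=exp_depression)
            v_exp_sd = (
                config.peak_measurement_error / exp_depression * v_exp
                if config.peak_measurement_error > 0
                else 0.0
            )
            k2_exp = rate_constants.k2_top_down(
                max(nr.k_prime, 0.0), R, v_exp, const,
                k_prime_sd=nr.k_prime_sd, v_sd=v_exp_sd,
            )
            exp_provenance = "trace plateau"
        else:
            k2_exp = k2_model
            exp_provenance = "model (plateau not observed)"

        per_size.append({
            "radius_cm": R,
            "radius_nm": cm_to_nm(R),
            "n_traces": len(by_radius[R]),
            "k_prime": nr.k_prime,
            "k_prime_sd": nr.k_prime_sd,
            "k_prime_r_squared": nr.r_squared,
            "k_prime_intercept": nr.intercept,
            "A_cm2_per_mmol": geo.per_mmol_area_A,
            "delta_I_max_model_uA": geo.max_depression_model,
            "delta_I_max_exp_uA": exp_depression,
            "delta_I_max_provenance": exp_provenance,
            "k2_model": k2_model.value,
            "k2_model_sd": k2_model.sd,
            "k2_exp": k2_exp.value,
            "k2_exp_sd": k2_exp.sd,
            "k2cor": k2c,
        })

    ratios = rate_constants.ratio_diagnostics(
        [kprime_by_radius[R].k_prime for R in radii],
        slope_fit.slope,
        radii,
        k2_model_vals,
        const,
        [kprime_by_radius[R].k_prime_sd for R in radii],
    )
    for row, r_kp, r_k2, r_sd in zip(
        per_size, ratios.ratio_kprime, ratios.ratio_k2, ratios.ratio_sd
    ):
        row["ratio_kprime"] = r_kp
        row["ratio_k2"] = r_k2
        row["ratio_sd"] = r_sd

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "constants": const.to_dict(),
        "rate_window_s": list(config.rate_window),
        "weighted_area_fit": config.weighted_area_fit,
        "per_size": per_size,
        "slope_fit": {
            "slope": slope_fit.slope,
            "slope_sd": slope_fit.slope_sd,
            "r_squared": slope_fit.r_squared,
            "intercept": slope_fit.intercept,
            "n_sizes": slope_fit.n_points,
        },
        "k1": {"value": k1.value, "sd": k1.sd},
        "k2cor": {"mean": k2cor.mean, "sd": k2cor.sd},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Load the manifest and traces, analyze, write report JSON + CSV.

    Nothing is written until the whole analysis has succeeded, so a
    failing run leaves no partial outputs.
    """
    logging.basicConfig(level=config.log_level)
    manifest = load_manifest(config.manifest_path)
    traces = load_traces(manifest, Path(config.manifest_path).parent)
    logger.info("loaded %d traces from %s", len(traces), config.manifest_path)

    report = analyze_traces(traces, config)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    pd.DataFrame(report["per_size"]).to_csv(out_dir / "per_size.csv", index=False)
    logger.info("report written to %s", report_path)
    return report
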