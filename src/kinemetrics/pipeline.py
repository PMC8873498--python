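"""Pipeline orchestration: keypoints -> per-infant features -> cohort reports.

``run_extract`` turns each infant's keypoint series into one feature row:
64 descriptive statistics (8 joints x {angle, velocity} x {max, min, mean,
sd}), 16 sample-entropy complexity indices and 56 pairwise similarity
entries (28 joint pairs x {angle, velocity}).  ``run_cohort`` joins features
to outcome records, splits on the HINE cut, and emits the report bundle:
index-outcome correlations, group comparisons of complexity indices,
descriptive and similarity group tables, a cohort-characteristics table and
a machine-readable JSON summary carrying every analytic parameter.

All emitted CSVs use fixed 6-significant-digit formatting, so a fixed input
and configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    HINE_CUT,
    assign_groups,
    build_cohort_table,
    compare_groups_continuous,
    correlate_with_outcome,
)
from .complexity import SampEnParams, complexity_indices
from .errors import InsufficientDataError, KinemetricsError, SmoothingError
from .joints import ANGLE_JOINTS
from .keypoint_io import KeypointSeries, filter_confidence, validate_series
from .kinematics import angle_series, angular_velocity, descriptive_stats, smooth_interpolate
from .similarity import similarity_matrix

__all__ = ["RunConfig", "extract_features", "run_extract", "run_cohort"]

log = logging.getLogger("kinemetrics")

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class RunConfig:
    """Analytic parameters for a pipeline run (all stamped into reports)."""

    frame_rate: float = 30.0
    conf_threshold: float = 0.5
    min_duration_s: float = 120.0
    max_missing_fraction: float = 0.30
    smoothing_span: float = 0.05
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    similarity_on_smoothed: bool = True
    test_method: str = "auto"  # for index group comparisons
    alpha: float = 0.05
    hine_cut: int = HINE_CUT
    fdr: bool = False

    @property
    def sampen(self) -> SampEnParams:
        return SampEnParams(m=self.sampen_m, r_factor=self.sampen_r_factor)


@dataclass
class InfantFeatures:
    infant_id: str
    features: dict[str, float]
    valid_joints: dict[str, bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def n_valid_joints(self) -> int:
        return sum(self.valid_joints.values())


def extract_features(series: KeypointSeries, config: RunConfig) -> InfantFeatures:
    """Full single-infant feature extraction.

    Confidence-filters the keypoints, computes each angle-bearing joint's
    raw angle series, smooths/interpolates it, derives the angular velocity,
    and collects descriptive statistics, sample-entropy indices and the two
    similarity matrices.  Joints that fail validation or smoothing are
    flagged and their features set to NaN; the rest are still computed.
    """
    filtered = filter_confidence(series, config.conf_threshold)
    report = validate_series(
        filtered,
        min_duration=config.min_duration_s,
        max_missing_fraction=config.max_missing_fraction,
    )
    feats: dict[str, float] = {}
    valid: dict[str, bool] = {}
    angles = {}
    velocities = {}
    for j in ANGLE_JOINTS:
        ok = report.angle_joint_ok[j]
        if ok:
            try:
                ang = smooth_interpolate(angle_series(filtered, j), span=config.smoothing_span)
                vel = angular_velocity(ang)
                angles[j] = ang
                velocities[j] = vel
            except (SmoothingError, InsufficientDataError) as exc:
                log.warning("%s %s: %s", series.infant_id, j.value, exc)
                ok = False
        valid[j.value] = ok
        if ok:
            astats = descriptive_stats(angles[j].smoothed)
            vstats = descriptive_stats(velocities[j].omega)
            feats[f"angle_max_{j.value}"] = astats.maximum
            feats[f"angle_min_{j.value}"] = astats.minimum
            feats[f"angle_mean_{j.value}"] = astats.mean
            feats[f"angle_sd_{j.value}"] = astats.sd
            feats[f"vel_max_{j.value}"] = vstats.maximum
            feats[f"vel_min_{j.value}"] = vstats.minimum
            feats[f"vel_mean_{j.value}"] = vstats.mean
            feats[f"vel_sd_{j.value}"] = vstats.sd
        else:
            for sig in ("angle", "vel"):
                for stat in ("max", "min", "mean", "sd"):
                    feats[f"{sig}_{stat}_{j.value}"] = float("nan")

    feats.update(
        complexity_indices(
            angles, velocities, params=config.sampen, infant_id=series.infant_id
        ).as_features()
    )

    n = filtered.n_frames
    nanrow = np.full(n, np.nan)
    ang_sig = {}
    vel_sig = {}
    for j in ANGLE_JOINTS:
        if valid[j.value]:
            ang_sig[j] = angles[j].smoothed if config.similarity_on_smoothed else angles[j].theta
            vel_sig[j] = velocities[j].omega
        else:
            ang_sig[j] = nanrow
            vel_sig[j] = nanrow
    feats.update(similarity_matrix(ang_sig, "angle", infant_id=series.infant_id).as_features())
    feats.update(similarity_matrix(vel_sig, "velocity", infant_id=series.infant_id).as_features())
    return InfantFeatures(
        infant_id=series.infant_id, features=feats, valid_joints=valid, reasons=report.reasons
    )


def run_extract(series_list: list[KeypointSeries], config: RunConfig) -> pd.DataFrame:
    """Feature table with one row per infant (index: infant_id).

    Infants with no valid angle-bearing joint are excluded with a logged
    reason; partially invalid infants keep their row with NaN features for
    the failed joints and a ``n_valid_joints`` column records how many of
    the 8 succeeded.
    """
    rows = []
    for series in series_list:
        feat = extract_features(series, config)
        if feat.n_valid_joints == 0:
            log.warning(
                "excluding %s: no valid angle-bearing joint (%s)",
                feat.infant_id,
                "; ".join(feat.reasons) or "unknown",
            )
            continue
        row = {"infant_id": feat.infant_id, "n_valid_joints": feat.n_valid_joints}
        row.update(feat.features)
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no infant produced any valid joint")
    return pd.DataFrame(rows).set_index("infant_id")


# ---------------------------------------------------------------------------
# cohort reports


def _se_columns() -> list[str]:
    cols = [f"se_angle_{j.value}" for j in ANGLE_JOINTS]
    cols += [f"se_vel_{j.value}" for j in ANGLE_JOINTS]
    return cols


def run_cohort(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame | dict]:
    """Cohort-level statistics and report bundle.

    Joins features to outcomes on infant_id (warning on unmatched ids),
    derives HINE groups, and produces:

    * ``correlation`` — Pearson r and p between each complexity index and
      the HINE global score;
    * ``group_comparison`` — mean (sd) per group and two-sided p for each
      complexity index;
    * ``descriptives_by_group`` — the same for the 64 descriptive statistics;
    * ``similarity_by_group`` — the same for the 56 similarity entries;
    * ``cohort`` — cohort-characteristics table from the outcome covariates;
    * ``summary`` — JSON-ready dict with methods, parameters and versions.

    With ``out_dir`` set, each table is written as CSV (6-significant-digit
    floats) plus ``summary.json``.
    """
    outcomes = outcomes.set_index("infant_id") if "infant_id" in outcomes.columns else outcomes
    common = features.index.intersection(outcomes.index)
    unmatched = len(features) - len(common) + len(outcomes) - len(common)
    if unmatched:
        log.warning(
            "%d unmatched infant ids (%d feature rows, %d outcome rows, %d joined)",
            unmatched,
            len(features),
            len(outcomes),
            len(common),
        )
    if len(common) < 3:
        raise InsufficientDataError(f"only {len(common)} infants join features to outcomes")
    feats = features.loc[common]
    outs = outcomes.loc[common]
    scores = outs["hine_global"].to_numpy(dtype=float)
    groups = assign_groups(scores, cut=config.hine_cut)
    n_low = int((groups == "low").sum())
    n_high = int((groups == "high").sum())
    if n_low == 0 or n_high == 0:
        empty = "low (HINE < %d)" % config.hine_cut if n_low == 0 else "high (HINE >= %d)" % config.hine_cut
        raise KinemetricsError(f"empty group: {empty} has no infants")

    se_cols = _se_columns()

    corr_rows = []
    for col in se_cols:
        vals = feats[col].to_numpy(dtype=float)
        n_pairs = int((np.isfinite(vals) & np.isfinite(scores)).sum())
        try:
            res = correlate_with_outcome(vals, scores)
            r, p = res.statistic, res.pvalue
        except InsufficientDataError:
            r, p = float("nan"), float("nan")
        corr_rows.append({"index": col, "r": r, "p": p, "n": n_pairs})
    correlation = pd.DataFrame(corr_rows)

    def group_table(cols: list[str]) -> pd.DataFrame:
        rows = []
        for col in cols:
            lo = feats.loc[groups == "low", col].to_numpy(dtype=float)
            hi = feats.loc[groups == "high", col].to_numpy(dtype=float)
            lo_f = lo[np.isfinite(lo)]
            hi_f = hi[np.isfinite(hi)]
            try:
                res = compare_groups_continuous(lo, hi, method=config.test_method)
                p, meth, stat = res.pvalue, res.method, res.statistic
            except InsufficientDataError:
                p, meth, stat = float("nan"), "not tested", float("nan")
            rows.append(
                {
                    "index": col,
                    "mean_low": lo_f.mean() if lo_f.size else float("nan"),
                    "sd_low": lo_f.std(ddof=1) if lo_f.size > 1 else float("nan"),
                    "mean_high": hi_f.mean() if hi_f.size else float("nan"),
                    "sd_high": hi_f.std(ddof=1) if hi_f.size > 1 else float("nan"),
                    "statistic": stat,
                    "p": p,
                    "method": meth,
                }
            )
        return pd.DataFrame(rows)

    group_comparison = group_table(se_cols)
    desc_cols = [
        f"{sig}_{stat}_{j.value}"
        for sig in ("angle", "vel")
        for stat in ("max", "min", "mean", "sd")
        for j in ANGLE_JOINTS
    ]
    descriptives_by_group = group_table(desc_cols)
    sim_cols = [c for c in feats.columns if c.startswith("rho_")]
    similarity_by_group = group_table(sim_cols)

    covariate_cont = [c for c in ("corrected_age_months",) if c in outs.columns]
    covariate_cat = [c for c in ("sex_female", "multiple_gestations") if c in outs.columns]
    cohort = build_cohort_table(
        outs.assign(hine_global=scores),
        continuous=["hine_global", *covariate_cont],
        categorical=covariate_cat,
        cut=config.hine_cut,
    )

    summary = {
        "software": {"package": "kinemetrics", "version": __version__},
        "parameters": asdict(config),
        "seed": seed,
        "n_infants": int(len(common)),
        "groups": {"low": n_low, "high": n_high, "cut": config.hine_cut},
        "units": {"angle": "degrees", "velocity": "degrees/second"},
        "methods": {
            "complexity": f"sample entropy, m={config.sampen_m}, r={config.sampen_r_factor}*sd, Chebyshev",
            "similarity": "Pearson correlation, pairwise deletion",
            "group_comparison": config.test_method,
            "correlation": "Pearson with two-sided t-based p",
            "multiple_testing": "benjamini-hochberg" if config.fdr else "none (per-test alpha)",
        },
        "alpha": config.alpha,
    }

    bundle: dict[str, pd.DataFrame | dict] = {
        "correlation": correlation,
        "group_comparison": group_comparison,
        "descriptives_by_group": descriptives_by_group,
        "similarity_by_group": similarity_by_group,
        "cohort": cohort,
        "summary": summary,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, obj in bundle.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out_dir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return bundle


def _setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
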