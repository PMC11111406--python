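"""Pooled-barcode viability screen processing.

The processing chain mirrors the standard multiplexed-barcode screen
pipeline: (1) build a per-plate reference profile from the ten spike-in
control barcodes in negative-control wells; (2) calibrate every well onto
that reference with a monotone smooth map fitted to the spike-in pairs;
(3) score each cell line's control separability (optimal-threshold error
rate and dynamic range) and filter; (4) convert calibrated signal to
log-viability against the per-plate negative-control median; (5) correct
residual batch effects with a parametric empirical-Bayes location-scale
adjustment; (6) collapse replicates to a treatment-level profile by the
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import isotonic_regression

__all__ = [
    "QCMetrics",
    "ScreenResult",
    "build_reference_profile",
    "calibrate_well",
    "control_separability",
    "apply_qc_filters",
    "compute_log_viability",
    "correct_batch_effects",
    "collapse_replicates",
    "process_screen",
]

ERROR_MAX = 0.05   # maximum tolerated control-classifier error rate
DR_MIN = 1.74      # minimum dynamic range (log2 units)


def build_reference_profile(plate: pd.DataFrame) -> pd.Series:
    """Median log2(MFI) of each spike-in barcode across negative-control wells.

    ``plate`` is the plate-table slice for one plate.  Returns a Series
    indexed by spike-in barcode id in abundance order.  Raises
    ``ValueError``, naming the offending well, if any negative-control well
    is missing a spike-in barcode.
    """
    neg = plate[plate["treatment"] == "negative_control"]
    if neg.empty:
        raise ValueError("plate has no negative-control wells")
    spikes = neg[neg["barcode_class"] == "spike"]
    spike_ids = sorted(plate.loc[plate["barcode_class"] == "spike",
                                 "barcode_id"].unique())
    for well_id, grp in spikes.groupby("well_id"):
        missing = set(spike_ids) - set(grp["barcode_id"])
        if missing:
            raise ValueError(
                f"negative-control well {well_id!r} is missing spike-in "
                f"barcode(s) {sorted(missing)}")
    ref = np.log2(spikes.groupby("barcode_id")["mfi"].median())
    return ref.reindex(spike_ids)


def _monotone_map(well_levels: np.ndarray, reference: np.ndarray):
    """Monotone smooth map g from well spike-in levels to reference levels.

    A shape-preserving cubic (PCHIP) through the calibration pairs, with the
    reference values isotonic-regressed first so the interpolant is
    guaranteed non-decreasing, and linear extrapolation beyond the data
    range using the endpoint slopes.
    """
    order = np.argsort(well_levels)
    x, y = well_levels[order], reference[order]
    # collapse tied well levels to their mean reference
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    if ux.size < 4:
        raise ValueError(
            f"insufficient calibration points: {ux.size} usable spike-in "
            "pairs (need >= 4)")
    uy = isotonic_regression(uy).x
    interp = PchipInterpolator(ux, uy, extrapolate=False)
    lo_slope = float(interp.derivative()(ux[0]))
    hi_slope = float(interp.derivative()(ux[-1]))

    def g(values):
        values = np.asarray(values, dtype=float)
        out = interp(values)
        below = values < ux[0]
        above = values > ux[-1]
        out[below] = uy[0] + lo_slope * (values[below] - ux[0])
        out[above] = uy[-1] + hi_slope * (values[above] - ux[-1])
        return out

    return g


def calibrate_well(well_spike_log2: Sequence[float],
                   reference: Sequence[float],
                   cell_log2: Sequence[float]) -> np.ndarray:
    """Map a well's cell-barcode log2(MFI) values onto the reference scale.

    ``well_spike_log2`` and ``reference`` are the ten paired spike-in levels
    (well measurement -> plate reference); the fitted monotone map is then
    applied to ``cell_log2``.  Order among cell barcodes is preserved
    (the map is non-decreasing).
    """
    g = _monotone_map(np.asarray(well_spike_log2, dtype=float),
                      np.asarray(reference, dtype=float))
    return g(cell_log2)


@dataclass
class QCMetrics:
    """Control-separability metrics for one cell line on one plate."""

    error_rate: float
    dynamic_range: float
    error_max: float = ERROR_MAX
    dr_min: float = DR_MIN
    passes: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passes = (self.error_rate <= self.error_max
                       and self.dynamic_range >= self.dr_min)


def control_separability(neg: Sequence[float], pos: Sequence[float],
                         error_max: float = ERROR_MAX,
                         dr_min: float = DR_MIN) -> QCMetrics:
    """Optimal-threshold classifier error and dynamic range of the controls.

    Everything below the threshold is called positive and above negative;
    the error rate is the minimum of (FP + FN) / n over all thresholds
    (candidates: midpoints between adjacent distinct values plus +-inf).
    Dynamic range is median(neg) - median(pos) in log2 units.
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both control sets must be non-empty")
    values = np.unique(np.concatenate([neg, pos]))
    mids = (values[:-1] + values[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # below threshold => called positive: FP = negatives below, FN = positives above
    fp = np.searchsorted(neg_sorted, candidates, side="left")
    fn = pos.size - np.searchsorted(pos_sorted, candidates, side="left")
    err = float((fp + fn).min() / (neg.size + pos.size))
    dr = float(np.median(neg) - np.median(pos))
    return QCMetrics(error_rate=err, dynamic_range=dr,
                     error_max=error_max, dr_min=dr_min)


def apply_qc_filters(qc: pd.DataFrame, error_max: float = ERROR_MAX,
                     dr_min: float = DR_MIN,
                     min_passing_replicates: int = 2) -> pd.DataFrame:
    """Per-line inclusion flags from per-(line, replicate) QC metrics.

    ``qc`` needs columns (cell_line, replicate, error_rate, dynamic_range).
    A replicate passes iff error_rate <= error_max and dynamic_range >=
    dr_min (boundary values pass); a line is included iff it has at least
    ``min_passing_replicates`` passing replicates.
    """
    qc = qc.copy()
    qc["passes"] = ((qc["error_rate"] <= error_max)
                    & (qc["dynamic_range"] >= dr_min))
    summary = qc.groupby("cell_line")["passes"].sum().rename("n_passing")
    out = summary.reset_index()
    out["included"] = out["n_passing"] >= min_passing_replicates
    return out


def compute_log_viability(corrected_log2, mu_minus_log2: float):
    """Log-viability: corrected log2(MFI) minus the negative-control median.

    Equivalent to log2(x_linear) - log2(mu_minus_linear) since both
    quantities are already on the log2 scale.
    """
    if not np.isfinite(mu_minus_log2):
        raise ValueError("negative-control median is not finite")
    return np.asarray(corrected_log2, dtype=float) - float(mu_minus_log2)


# ---------------------------------------------------------------------------
# Parametric empirical-Bayes batch correction (location-scale, ComBat-style)


def _eb_iterate(z: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
                gamma_bar: float, tau2: float, a_prior: float, b_prior: float,
                n_b: int, conv: float = 1e-4, max_iter: int = 500):
    """Iterative solution of the parametric posterior means (per batch)."""
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    ssq = lambda g: ((z - g[:, None]) ** 2).sum(axis=1)
    for _ in range(max_iter):
        gamma_new = (n_b * tau2 * gamma_hat + delta * gamma_bar) / (
            n_b * tau2 + delta)
        delta_new = (b_prior + 0.5 * ssq(gamma_new)) / (
            n_b / 2.0 + a_prior - 1.0)
        change = max(np.abs(gamma_new - gamma).max(initial=0.0),
                     np.abs(delta_new - delta).max(initial=0.0))
        gamma, delta = gamma_new, delta_new
        if change < conv:
            break
    return gamma, delta


def correct_batch_effects(matrix: pd.DataFrame,
                          batch: Sequence) -> pd.DataFrame:
    """Parametric empirical-Bayes location-scale batch adjustment.

    ``matrix`` is features x samples; ``batch`` labels the samples
    (columns).  Per feature the data are standardized against the
    sample-size-weighted grand mean and pooled variance, per-batch additive
    and multiplicative effects are estimated and shrunk toward across-batch
    priors, and the data are back-transformed.  After adjustment each
    feature is recentred so its grand mean is preserved exactly.

    A single batch (or all-singleton batches) passes the matrix through
    unchanged with a warning; an individual singleton batch falls back to a
    location-only adjustment (its scale effect is not estimable) with a
    warning.
    """
    x = matrix.to_numpy(dtype=float)
    batch = pd.Series(list(batch), index=matrix.columns)
    levels = batch.unique()
    if len(batch) != matrix.shape[1]:
        raise ValueError("batch labels must align with matrix columns")
    if len(levels) <= 1:
        warnings.warn("single batch: nothing to correct", stacklevel=2)
        return matrix.copy()
    groups = {lv: np.flatnonzero((batch == lv).to_numpy()) for lv in levels}
    if all(len(ix) < 2 for ix in groups.values()):
        warnings.warn("all batches are singletons: passing through",
                      stacklevel=2)
        return matrix.copy()

    n = x.shape[1]
    batch_means = {lv: x[:, ix].mean(axis=1) for lv, ix in groups.items()}
    grand = sum(len(ix) / n * batch_means[lv] for lv, ix in groups.items())
    resid = x - np.column_stack([batch_means[batch.iloc[j]]
                                 for j in range(n)])
    var_pooled = (resid ** 2).sum(axis=1) / n
    keep = var_pooled > 1e-12 * max(1.0, np.abs(x).max())
    scale = np.where(keep, np.sqrt(var_pooled), 1.0)
    z = (x - grand[:, None]) / scale[:, None]

    adjusted = z.copy()
    for lv, ix in groups.items():
        zb = z[:, ix]
        gamma_hat = zb.mean(axis=1)
        if len(ix) < 2:
            warnings.warn(
                f"batch {lv!r} has a single sample: location-only adjustment",
                stacklevel=2)
            adjusted[:, ix] = zb - gamma_hat[:, None]
            continue
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        m, s2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
        if s2 <= 0 or tau2 <= 0:
            # degenerate hyperpriors (e.g. a single feature): no shrinkage
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            a_prior = (2.0 * s2 + m ** 2) / s2
            b_prior = (m * s2 + m ** 3) / s2
            gamma_star, delta_star = _eb_iterate(
                zb, gamma_hat, delta_hat, gamma_bar, tau2,
                a_prior, b_prior, len(ix))
            delta_star = np.maximum(delta_star, 1e-12)
        adjusted[:, ix] = (zb - gamma_star[:, None]) / np.sqrt(
            delta_star)[:, None]

    out = adjusted * scale[:, None] + grand[:, None]
    out[~keep] = x[~keep]
    # preserve each feature's grand mean exactly
    out += (x.mean(axis=1) - out.mean(axis=1))[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_replicates(viability: pd.DataFrame) -> pd.DataFrame:
    """Median log-viability across replicates per (line, treatment, dose)."""
    return (viability
            .groupby(["cell_line", "treatment", "dose_molar"], sort=True)
            ["log_viability"].median().reset_index())


# ---------------------------------------------------------------------------
# Full chain


@dataclass
class ScreenResult:
    """Outputs of the full screen-processing chain."""

    qc: pd.DataFrame          # per (cell_line, replicate) metrics + pass flag
    inclusion: pd.DataFrame   # per cell_line: n_passing, included
    viability: pd.DataFrame   # long per-well log-viability (QC-passing lines)
    collapsed: pd.DataFrame   # treatment-level median profile


def _calibrate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Spike-in calibration of every well on one plate (all barcodes)."""
    ref = build_reference_profile(plate)
    out = []
    for well_id, grp in plate.groupby("well_id", sort=False):
        spikes = grp[grp["barcode_class"] == "spike"].set_index("barcode_id")
        well_levels = np.log2(spikes["mfi"].reindex(ref.index).to_numpy())
        cells = grp[grp["barcode_class"] == "cell"].copy()
        cells["log2_corrected"] = calibrate_well(
            well_levels, ref.to_numpy(), np.log2(cells["mfi"].to_numpy()))
        out.append(cells)
    return pd.concat(out, ignore_index=True)


def process_screen(plate_table: pd.DataFrame,
                   error_max: float = ERROR_MAX,
                   dr_min: float = DR_MIN,
                   min_passing_replicates: int = 2,
                   batch_correct: bool = True,
                   batch_key: str = "batch") -> ScreenResult:
    """Run the full chain: calibrate, QC, log-viability, batch-correct, collapse.

    The replicate key is the ``replicate`` column (one plate per pool and
    replicate).  Batch correction treats cell lines as samples and
    (treatment, dose, replicate) as features, with each line's batch taken
    from ``batch_key`` (pool and culture-condition effects combined into
    one label upstream).
    """
    required = {"plate_id", "well_id", "treatment", "dose_molar", "replicate",
                "barcode_id", "barcode_class", "mfi", batch_key}
    missing = required - set(plate_table.columns)
    if missing:
        raise ValueError(f"plate table is missing columns {sorted(missing)}")

    calibrated = pd.concat(
        [_calibrate_plate(grp) for _, grp in
         plate_table.groupby("plate_id", sort=True)],
        ignore_index=True)
    calibrated = calibrated.rename(columns={"barcode_id": "cell_line"})

    # QC per (line, replicate plate)
    qc_rows = []
    for (line, plate_id), grp in calibrated.groupby(
            ["cell_line", "plate_id"], sort=True):
        neg = grp.loc[grp["treatment"] == "negative_control", "log2_corrected"]
        pos = grp.loc[grp["treatment"] == "positive_control", "log2_corrected"]
        if neg.empty or pos.empty:
            continue
        m = control_separability(neg.to_numpy(), pos.to_numpy(),
                                 error_max=error_max, dr_min=dr_min)
        rep = grp["replicate"].iloc[0]
        qc_rows.append((line, plate_id, rep, m.error_rate, m.dynamic_range,
                        m.passes))
    qc = pd.DataFrame(qc_rows, columns=[
        "cell_line", "plate_id", "replicate", "error_rate", "dynamic_range",
        "passes"])
    inclusion = apply_qc_filters(qc, error_max=error_max, dr_min=dr_min,
                                 min_passing_replicates=min_passing_replicates)

    passing = qc.loc[qc["passes"], ["cell_line", "plate_id"]]
    included_lines = set(inclusion.loc[inclusion["included"], "cell_line"])
    keep = calibrated.merge(passing, on=["cell_line", "plate_id"])
    keep = keep[keep["cell_line"].isin(included_lines)]

    # log-viability vs per-plate, per-line negative-control median
    mu_minus = (keep[keep["treatment"] == "negative_control"]
                .groupby(["cell_line", "plate_id"])["log2_corrected"]
                .median().rename("mu_minus"))
    treated = keep[keep["treatment"] == "drug"].merge(
        mu_minus.reset_index(), on=["cell_line", "plate_id"])
    treated["log_viability"] = (treated["log2_corrected"]
                                - treated["mu_minus"])

    viability = treated[["cell_line", batch_key, "treatment", "dose_molar",
                         "replicate", "plate_id", "log_viability"]].copy()

    if batch_correct and viability["cell_line"].nunique() > 1:
        wide = viability.pivot_table(
            index=["treatment", "dose_molar", "replicate"],
            columns="cell_line", values="log_viability")
        batches = (viability.drop_duplicates("cell_line")
                   .set_index("cell_line")[batch_key]
                   .reindex(wide.columns))
        if batches.nunique() > 1 and not wide.isna().any().any():
            corrected = correct_batch_effects(wide, batches)
            long = corrected.stack().rename("log_viability").reset_index()
            viability = long.merge(
                viability.drop(columns="log_viability"),
                on=["cell_line", "treatment", "dose_molar", "replicate"])

    collapsed = collapse_replicates(viability)
    collapsed["viability_fraction"] = np.clip(
        2.0 ** collapsed["log_viability"], 0.0, 1.2)
    return ScreenResult(qc=qc, inclusion=inclusion, viability=viability,
                        collapsed=collapsed)
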