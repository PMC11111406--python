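"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators are provided:

* ``simulate_screen`` — pooled-barcode viability plates: every well carries
  ten spike-in control barcodes at fixed increasing abundances plus the
  cell-line barcodes of its pool; true viability follows known 4PL curves;
  measurement noise is multiplicative lognormal on linear MFI (so additive
  Gaussian on log2 MFI); well-level detection offsets and per-pool batch
  shifts are injected so the calibration and batch-correction stages have
  something real to remove.
* ``simulate_cnv_sample`` — Poisson-distributed binned read counts over a
  synthetic chromosome with a smooth GC bias and implanted copy-ratio
  events.
* ``simulate_dose_matrix`` — two-drug viability grids whose combined
  inhibition follows Bliss independence plus a tunable interaction excess.
* ``simulate_pkpd`` — one-compartment oral PK curves linked to a sigmoid
  PD response.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dose_response import curve_auc, four_pl

__all__ = [
    "ScreenSimConfig",
    "CnvSimConfig",
    "simulate_screen",
    "simulate_cnv_sample",
    "simulate_dose_matrix",
    "simulate_pkpd",
]

N_SPIKES = 10


def _default_doses() -> np.ndarray:
    # 8-point, 3-fold dilution series from 1 uM down (molar).
    return 1e-6 / 3.0 ** np.arange(8)


def _default_spike_levels() -> np.ndarray:
    # 10 increasing abundances (linear MFI units), ~2x apart.
    return 64.0 * 2.0 ** np.arange(N_SPIKES)


@dataclass
class ScreenSimConfig:
    """Study design for a simulated pooled-barcode viability screen.

    ``true_params`` may be a DataFrame with columns (a, b, s, ec50) and one
    row per cell line; when omitted, realistic parameters are sampled:
    a = 1, b ~ U(0, 0.35), s ~ U(1, 3), ec50 log-uniform over the middle of
    the dose window.  ``batch_shift`` gives the additive log2-MFI offset
    applied to cell barcodes in treatment wells of each batch (pools are
    assigned to batches round-robin); it is the effect the empirical-Bayes
    batch corrector is asked to remove downstream.
    """

    n_cell_lines: int = 20
    n_pools: int = 2
    n_batches: int = 1
    spike_in_levels: np.ndarray = field(default_factory=_default_spike_levels)
    true_params: Optional[pd.DataFrame] = None
    doses: np.ndarray = field(default_factory=_default_doses)
    n_replicates: int = 3
    noise_cv: float = 0.1
    batch_shift: Union[float, Sequence[float]] = 0.0
    well_effect_sd: float = 0.3
    n_negative_wells: int = 6
    n_positive_wells: int = 4
    baseline_log2_mfi: float = 12.5
    baseline_log2_sd: float = 0.5
    positive_control_viability: float = 0.05  # not 0: keeps log2 defined
    seed: int = 0

    def validate(self) -> None:
        levels = np.asarray(self.spike_in_levels, dtype=float)
        if levels.size != N_SPIKES or np.any(np.diff(levels) <= 0):
            raise ValueError("spike_in_levels must be 10 strictly increasing values")
        doses = np.asarray(self.doses, dtype=float)
        diffs = np.diff(doses)
        if np.any(doses <= 0) or not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("doses must be positive and strictly monotone")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_cell_lines < 1 or self.n_pools < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")
        if self.noise_cv < 0 or self.well_effect_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0 < self.positive_control_viability < 1):
            raise ValueError("positive_control_viability must be in (0, 1)")


def _sample_true_params(n: int, doses: np.ndarray,
                        rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = doses.min(), doses.max()
    ec50 = np.exp(rng.uniform(np.log(lo * 3), np.log(hi / 3), size=n))
    return pd.DataFrame({
        "a": np.ones(n),
        "b": rng.uniform(0.0, 0.35, size=n),
        "s": rng.uniform(1.0, 3.0, size=n),
        "ec50": ec50,
    })


def _batch_offsets(batch_shift, n_batches: int) -> np.ndarray:
    arr = np.asarray(batch_shift, dtype=float)
    if arr.ndim == 0:
        # scalar: batch 0 unshifted, later batches shifted by the scalar
        out = np.zeros(n_batches)
        out[1:] = float(arr)
        return out
    if arr.size != n_batches:
        raise ValueError("batch_shift must be scalar or length n_batches")
    return arr


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a plate table and its ground-truth table.

    Returns ``(plate_table, truth)``.  The plate table has one row per
    (well, barcode) with columns plate_id, well_id, batch, pool, treatment,
    dose_molar, replicate, barcode_id, barcode_class and mfi.  Treatments
    are the drug label plus 'negative_control' (vehicle) and
    'positive_control' (lethal) wells on every plate.  The truth table
    records each line's 4PL parameters and the implied AUC over the tested
    dose window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses, dtype=float)
    spike_levels = np.asarray(config.spike_in_levels, dtype=float)
    spike_log2 = np.log2(spike_levels)

    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    pools = np.arange(config.n_cell_lines) % config.n_pools
    truth = (config.true_params.copy() if config.true_params is not None
             else _sample_true_params(config.n_cell_lines, doses, rng))
    truth = truth.reset_index(drop=True)
    if len(truth) != config.n_cell_lines:
        raise ValueError("true_params must have one row per cell line")
    truth.insert(0, "cell_line", lines)
    truth["pool"] = pools
    baseline_log2 = rng.normal(config.baseline_log2_mfi,
                               config.baseline_log2_sd, size=config.n_cell_lines)
    truth["baseline_mfi"] = 2.0 ** baseline_log2
    truth["auc"] = [
        curve_auc((r.a, r.b, r.s, r.ec50), doses.min(), doses.max())
        for r in truth.itertuples()
    ]

    offsets = _batch_offsets(config.batch_shift, config.n_batches)
    sigma_log2 = np.sqrt(np.log1p(config.noise_cv ** 2)) / np.log(2.0)
    spike_ids = [f"SPIKE{i + 1:02d}" for i in range(N_SPIKES)]

    records: list[tuple] = []
    for pool in range(config.n_pools):
        batch = pool % config.n_batches
        members = np.flatnonzero(pools == pool)
        for rep in range(config.n_replicates):
            plate_id = f"P{pool:02d}R{rep}"
            wells = (
                [(f"T{k:02d}", "drug", doses[k]) for k in range(doses.size)]
                + [(f"NC{j:02d}", "negative_control", 0.0)
                   for j in range(config.n_negative_wells)]
                + [(f"PC{j:02d}", "positive_control", 0.0)
                   for j in range(config.n_positive_wells)]
            )
            for well_id, treatment, dose in wells:
                well_off = (rng.normal(0.0, config.well_effect_sd)
                            if config.well_effect_sd > 0 else 0.0)
                # spike-ins: identical in expectation across wells
                for sid, s_log2 in zip(spike_ids, spike_log2):
                    noise = (rng.normal(0.0, sigma_log2)
                             if config.noise_cv > 0 else 0.0)
                    records.append((plate_id, well_id, batch, pool, treatment,
                                    dose, rep, sid, "spike",
                                    2.0 ** (s_log2 + well_off + noise)))
                for li in members:
                    if treatment == "drug":
                        v = float(four_pl(dose, truth.at[li, "a"],
                                          truth.at[li, "b"], truth.at[li, "s"],
                                          truth.at[li, "ec50"]))
                        shift = offsets[batch]
                    elif treatment == "negative_control":
                        v, shift = 1.0, 0.0
                    else:
                        v, shift = config.positive_control_viability, 0.0
                    noise = (rng.normal(0.0, sigma_log2)
                             if config.noise_cv > 0 else 0.0)
                    log2_mfi = (baseline_log2[li] + np.log2(v)
                                + well_off + shift + noise)
                    records.append((plate_id, well_id, batch, pool, treatment,
                                    dose, rep, lines[li], "cell",
                                    2.0 ** log2_mfi))

    plate = pd.DataFrame.from_records(records, columns=[
        "plate_id", "well_id", "batch", "pool", "treatment", "dose_molar",
        "replicate", "barcode_id", "barcode_class", "mfi",
    ])
    return plate, truth


# ---------------------------------------------------------------------------
# Sparse copy-number data


@dataclass
class CnvSimConfig:
    """Design of one simulated sparse-sequencing copy-number sample.

    ``events`` is a list of (start_bin, end_bin, copy_ratio) with half-open
    bin intervals.  ``gc_bias`` is either None (no bias), a sequence of
    polynomial coefficients evaluated at the per-bin GC fraction (highest
    power first, normalized to mean 1 across bins), or a callable gc -> bias.
    The desk-scale default genome is a single 2,000-bin chromosome; studies
    at full scale would use 20,000 bins of ~100 kb.
    """

    n_bins: int = 2000
    bin_width: int = 100_000
    gc: Optional[np.ndarray] = None
    events: Sequence[tuple[int, int, float]] = field(default_factory=list)
    mean_depth: float = 100.0
    gc_bias: Union[None, Sequence[float], Callable] = None
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins < 1 or self.bin_width < 1:
            raise ValueError("n_bins and bin_width must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for start, end, ratio in self.events:
            if not (0 <= start < end <= self.n_bins):
                raise ValueError(f"event ({start}, {end}) outside [0, n_bins)")
            if ratio <= 0:
                raise ValueError("copy_ratio must be positive")


def _default_gc(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    x = np.arange(n_bins)
    phase = rng.uniform(0, 2 * np.pi)
    gc = (0.45 + 0.06 * np.sin(2 * np.pi * x / n_bins * 3 + phase)
          + 0.04 * np.sin(2 * np.pi * x / n_bins * 11 + 2 * phase)
          + rng.normal(0, 0.01, size=n_bins))
    return np.clip(gc, 0.2, 0.8)


def simulate_cnv_sample(config: CnvSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-bin read counts and the true segment table.

    Counts are Poisson with mean ``mean_depth * copy_ratio(bin) *
    gc_bias(gc(bin))``.  Returns ``(bins, true_segments)`` where bins has
    columns (chrom, start, end, gc, count) in 0-based half-open bp
    coordinates and true_segments lists the piecewise-constant copy-ratio
    runs as (start_bin, end_bin, copy_ratio).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_bins
    gc = (np.asarray(config.gc, dtype=float) if config.gc is not None
          else _default_gc(n, rng))
    if gc.size != n or np.any((gc <= 0) | (gc >= 1)):
        raise ValueError("gc must have n_bins values strictly inside (0, 1)")

    ratio = np.ones(n)
    for start, end, r in config.events:
        ratio[start:end] = r

    if config.gc_bias is None:
        bias = np.ones(n)
    elif callable(config.gc_bias):
        bias = np.asarray(config.gc_bias(gc), dtype=float)
    else:
        bias = np.polyval(np.asarray(config.gc_bias, dtype=float), gc)
    if np.any(bias <= 0):
        raise ValueError("gc_bias must be positive over the GC range")
    bias = bias / bias.mean()

    counts = rng.poisson(config.mean_depth * ratio * bias)
    starts = np.arange(n) * config.bin_width
    bins = pd.DataFrame({
        "chrom": config.chrom,
        "start": starts,
        "end": starts + config.bin_width,
        "gc": gc,
        "count": counts,
    })

    change = np.flatnonzero(np.diff(ratio) != 0) + 1
    bounds = np.concatenate([[0], change, [n]])
    true_segments = pd.DataFrame({
        "start_bin": bounds[:-1],
        "end_bin": bounds[1:],
        "copy_ratio": ratio[bounds[:-1]],
    })
    return bins, true_segments


# ---------------------------------------------------------------------------
# Drug-combination dose matrices


def simulate_dose_matrix(doses_a: Sequence[float], doses_b: Sequence[float],
                         inhibition_a: Sequence[float],
                         inhibition_b: Sequence[float],
                         interaction: Union[float, np.ndarray] = 0.0,
                         noise_cv: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Two-drug viability grid under Bliss independence plus interaction.

    Single-agent inhibitions must lie in [0, 1].  The combined inhibition at
    dose pair (i, j) is ``eA_i + eB_j - eA_i * eB_j + interaction_ij``
    clipped to [0, 1]; viability = 1 - inhibition, with optional lognormal
    noise.  The returned DataFrame is viability indexed by drug-A dose
    (rows) and drug-B dose (columns), each including the zero dose, so the
    Bliss scorer downstream can read its single-agent margins from it.
    ``interaction`` may be a scalar or an (nA, nB) array over the nonzero
    dose pairs; positive values create synergy.
    """
    eA = np.asarray(inhibition_a, dtype=float)
    eB = np.asarray(inhibition_b, dtype=float)
    if np.any((eA < 0) | (eA > 1)) or np.any((eB < 0) | (eB > 1)):
        raise ValueError("single-agent inhibitions must lie in [0, 1]")
    dA = np.asarray(doses_a, dtype=float)
    dB = np.asarray(doses_b, dtype=float)
    if dA.size != eA.size or dB.size != eB.size:
        raise ValueError("doses and inhibitions must align")
    inter = np.broadcast_to(np.asarray(interaction, dtype=float),
                            (dA.size, dB.size))

    rows = np.concatenate([[0.0], dA])
    cols = np.concatenate([[0.0], dB])
    e = np.zeros((rows.size, cols.size))
    e[1:, 0] = eA
    e[0, 1:] = eB
    e[1:, 1:] = np.clip(eA[:, None] + eB[None, :] - eA[:, None] * eB[None, :]
                        + inter, 0.0, 1.0)
    viability = 1.0 - e
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        viability = viability * np.exp(rng.normal(0.0, sigma, viability.shape))
        viability = np.clip(viability, 0.0, 1.2)
    return pd.DataFrame(viability, index=pd.Index(rows, name="dose_a"),
                        columns=pd.Index(cols, name="dose_b"))


# ---------------------------------------------------------------------------
# One-compartment PK with sigmoid PD


def one_compartment_conc(t, dose: float, ka: float, ke: float, v: float):
    """Oral one-compartment concentration C(t) for a unit-bioavailable dose.

    C(t) = D ka / (V (ka - ke)) (e^{-ke t} - e^{-ka t}); the ka -> ke limit
    D ka t e^{-ka t} / V is used when the rate constants coincide.
    """
    t = np.asarray(t, dtype=float)
    if min(ka, ke, v) <= 0:
        raise ValueError("rate constants and volume must be positive")
    if abs(ka - ke) < 1e-12 * max(ka, ke):
        return dose * ka * t * np.exp(-ka * t) / v
    return dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def simulate_pkpd(dose_levels: Sequence[float], ka: float, ke: float, v: float,
                  ec50_pd: float, hill: float, times: Sequence[float],
                  noise_cv: float = 0.0, seed: int = 0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-concentration and time-response tables for several dose levels.

    Response is the fraction of the vehicle-level readout remaining:
    r = 1 / (1 + (C / ec50_pd)^hill), so r = 1 at C = 0 and r = 0.5 at
    C = ec50_pd.  Returns ``(pk, pd_resp)`` long tables with columns
    (dose, time_h, concentration) and (dose, time_h, response).
    """
    if ec50_pd <= 0 or hill <= 0:
        raise ValueError("ec50_pd and hill must be positive")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    pk_rows, pd_rows = [], []
    for dose in dose_levels:
        conc = one_compartment_conc(t, dose, ka, ke, v)
        if sigma > 0:
            conc = conc * np.exp(rng.normal(0.0, sigma, conc.shape))
        resp = 1.0 / (1.0 + (conc / ec50_pd) ** hill)
        if sigma > 0:
            resp = np.clip(resp * np.exp(rng.normal(0.0, sigma, resp.shape)),
                           0.0, 1.2)
        for ti, ci, ri in zip(t, conc, resp):
            pk_rows.append((dose, ti, ci))
            pd_rows.append((dose, ti, ri))
    pk = pd.DataFrame(pk_rows, columns=["dose", "time_h", "concentration"])
    pd_resp = pd.DataFrame(pd_rows, columns=["dose", "time_h", "response"])
    return pk, pd_resp
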