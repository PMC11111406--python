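"""Sparse whole-genome copy-number pipeline.

Binned read counts are corrected for GC bias with LOWESS, normalized
relative to the mean of the genome (copy number is relative throughout —
no ploidy or purity estimation), segmented with circular binary
segmentation (CBS), and segments are classified as focal or broad gains.
A cohort-level gain-frequency comparison uses the two-sided Fisher exact
test.

CBS here is the exhaustive form: on each interval the pair of circular
breakpoints maximizing a mean-shift statistic between the inside and
outside arcs is found by scanning all pairs, and the split is accepted if
its within-interval permutation p-value is at or below ``alpha``.  The
permutation loop is vectorized and stops early once significance is no
longer attainable, which keeps null intervals cheap.  The statistic uses
the interval's overall standard deviation (which is permutation-invariant)
as its scale:

    T(i, j) = |mean(x[i:j]) - mean(rest)| / (sd * sqrt(1/k + 1/(n-k)))

Complexity is O(n^2) breakpoint pairs per interval, suitable for the
few-thousand-bin profiles this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "Segment",
    "gc_correct",
    "normalize_to_genome_mean",
    "segment_cbs",
    "call_focal_gains",
    "annotate_genes",
    "compare_gain_frequency",
    "call_sample",
    "write_seg",
    "read_bins",
]

GAIN_RATIO_THRESHOLD = 1.5   # segment mean ratio above which a gain is called
FOCALITY_LIMIT_BP = 20_000_000  # gains longer than this are broad, not focal


def gc_correct(counts: Sequence[float], gc: Sequence[float],
               frac: float = 0.3, eps: float = 1e-6) -> np.ndarray:
    """Divide out the LOWESS trend of count against GC fraction.

    ``corrected(i) = count(i) / max(eps, trend(gc_i)) * mean(count)``, then
    rescaled so the overall mean is preserved exactly.  Requires at least
    50 bins with positive counts and GC strictly inside (0, 1).
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if counts.shape != gc.shape:
        raise ValueError("counts and gc must align")
    if np.all(counts == 0):
        raise ValueError("all counts are zero")
    if (counts > 0).sum() < 50:
        raise ValueError("need >= 50 bins with positive counts")
    if np.any((gc <= 0) | (gc >= 1)):
        raise ValueError("gc fractions must lie strictly inside (0, 1)")
    trend = lowess(counts, gc, frac=frac, return_sorted=False)
    mean = counts.mean()
    corrected = counts / np.maximum(trend, eps * mean) * mean
    return corrected * (mean / corrected.mean())


def normalize_to_genome_mean(corrected: Sequence[float]) -> np.ndarray:
    """Per-bin ratios relative to the genome mean (so mean(ratio) = 1)."""
    corrected = np.asarray(corrected, dtype=float)
    mean = corrected.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("genome mean must be positive")
    return corrected / mean


# ---------------------------------------------------------------------------
# Circular binary segmentation


@dataclass
class Segment:
    """Half-open bin interval with its mean ratio."""

    start: int
    end: int
    mean: float

    @property
    def n_bins(self) -> int:
        return self.end - self.start


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All circular breakpoint pairs 0 <= i < j <= n with 1 <= j-i <= n-1."""
    i, j = np.triu_indices(n + 1, k=1)
    keep = (j - i) < n
    return i[keep], j[keep]


def _stat_weights(n: int, sd: float, i: np.ndarray, j: np.ndarray):
    """Per-pair weight c so that T(i, j) = |n*arc - k*total| * c.

    Algebraically identical to |mean_in - mean_out| / (sd*sqrt(1/k+1/(n-k)))
    but needs only one multiply per pair per permutation.
    """
    k = (j - i).astype(float)
    c = 1.0 / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)) * k * (n - k))
    return k, c


def max_circular_stat(x: np.ndarray) -> tuple[int, int, float]:
    """Best circular breakpoint pair by exhaustive scan.

    Returns (i, j, T) where the arc [i, j) maximizes the mean-shift
    statistic against its complement.  Ties break on the first pair in
    (i, j) lexicographic order.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std()
    i, j = _pair_indices(n)
    if sd == 0:
        return int(i[0]), int(j[0]), 0.0
    s = np.concatenate([[0.0], np.cumsum(x)])
    k, c = _stat_weights(n, sd, i, j)
    arc = s[j] - s[i]
    t = np.abs(n * arc - k * s[n]) * c
    best = int(np.argmax(t))
    return int(i[best]), int(j[best]), float(t[best])


def _perm_pvalue(x: np.ndarray, observed: float, n_perm: int, alpha: float,
                 rng: np.random.Generator) -> float:
    """Permutation p-value of the max circular statistic, with early stop.

    p = (1 + #{perm max >= observed}) / (1 + #perms run).  The loop stops
    as soon as enough exceedances have accumulated that p > alpha is
    guaranteed at the full n_perm, so null intervals are cheap.
    """
    n = x.size
    sd = x.std()  # permutation-invariant
    i, j = _pair_indices(n)
    k, c = _stat_weights(n, sd, i, j)
    k32 = k.astype(np.float32)
    c32 = c.astype(np.float32)
    stop_at = int(np.floor(alpha * (n_perm + 1)))  # exceed > this => p > alpha
    cap = max(1, min(250, int(24_000_000 // max(1, i.size))))
    exceed, done = 0, 0
    tot = np.float32(x.sum())
    thresh = np.float32(observed * (1.0 - 1e-6))
    while done < n_perm:
        # small first chunk, growing to cap: null intervals stop early
        b = min(cap, n_perm - done, max(60, done))
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        s = np.cumsum(perms, axis=1, dtype=np.float32)
        s = np.concatenate([np.zeros((b, 1), dtype=np.float32), s], axis=1)
        t = s[:, j] - s[:, i]
        t *= np.float32(n)
        t -= k32 * tot
        np.abs(t, out=t)
        t *= c32
        exceed += int((t.max(axis=1) >= thresh).sum())
        done += b
        if exceed > stop_at:
            break
    return (1 + exceed) / (1 + done)


def _recurse(x: np.ndarray, offset: int, alpha: float, n_perm: int,
             rng: np.random.Generator, out: list[tuple[int, int]],
             min_width: int = 1) -> None:
    n = x.size
    if n < 3 or x.std() == 0:
        out.append((offset, offset + n))
        return
    i, j, t_obs = max_circular_stat(x)
    if t_obs <= 0 or (i == 0 and j == n):
        out.append((offset, offset + n))
        return
    p = _perm_pvalue(x, t_obs, n_perm, alpha, rng)
    if p > alpha:
        out.append((offset, offset + n))
        return
    for a, b in ((0, i), (i, j), (j, n)):
        if b - a >= 1:
            _recurse(x[a:b], offset + a, alpha, n_perm, rng, out, min_width)


def segment_cbs(ratios: Sequence[float], alpha: float = 0.01,
                n_perm: int = 1000, seed: int = 0,
                min_seg_delta: float = 0.1,
                log_scale: bool = False) -> list[Segment]:
    """Circular binary segmentation of one chromosome's ratio track.

    Recursively splits at the best circular breakpoint pair whenever the
    within-interval permutation p-value is <= ``alpha``; adjacent output
    segments whose means differ by less than ``min_seg_delta`` are merged.
    ``log_scale=True`` segments log2(ratio) instead of the linear ratio
    (segment means are always reported on the linear scale).  Deterministic
    given ``seed``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 3:
        raise ValueError("need at least 3 bins per chromosome")
    x = np.log2(np.maximum(ratios, 1e-6)) if log_scale else ratios
    rng = np.random.default_rng(seed)
    bounds: list[tuple[int, int]] = []
    _recurse(x, 0, alpha, n_perm, rng, bounds)
    bounds.sort()

    # merge adjacent segments with nearly equal means
    merged = [list(bounds[0])]
    for a, b in bounds[1:]:
        prev = merged[-1]
        if abs(ratios[prev[0]:prev[1]].mean() - ratios[a:b].mean()) \
                < min_seg_delta:
            prev[1] = b
        else:
            merged.append([a, b])
    return [Segment(a, b, float(ratios[a:b].mean())) for a, b in merged]


# ---------------------------------------------------------------------------
# Focal event calling and annotation


def call_focal_gains(segments: pd.DataFrame,
                     ratio_threshold: float = GAIN_RATIO_THRESHOLD,
                     focality_limit: float = FOCALITY_LIMIT_BP) -> pd.DataFrame:
    """Classify segments as focal_gain, broad_gain or none.

    A focal gain requires mean_ratio strictly above ``ratio_threshold`` and
    physical length at most ``focality_limit`` bp; gains exceeding the
    length limit are broad.  ``segments`` needs columns (chrom, start, end,
    mean_ratio); start/end are bp, half-open.
    """
    out = segments.copy()
    length = out["end"] - out["start"]
    gain = out["mean_ratio"] > ratio_threshold
    out["event_class"] = np.where(
        gain & (length <= focality_limit), "focal_gain",
        np.where(gain, "broad_gain", "none"))
    return out


def annotate_genes(events: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping gene names to each event (half-open intervals).

    ``genes`` follows BED conventions: columns (chrom, start, end, name),
    0-based half-open.  A gene is listed when it overlaps the event by at
    least 1 bp.
    """
    required = {"chrom", "start", "end", "name"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    if ((genes["end"] <= genes["start"]).any()
            or (genes["start"] < 0).any()):
        raise ValueError("malformed gene intervals")
    out = events.copy()
    hits = []
    for ev in out.itertuples():
        same = genes[genes["chrom"] == ev.chrom]
        overlap = same[(same["start"] < ev.end) & (same["end"] > ev.start)]
        hits.append(",".join(overlap["name"].tolist()))
    out["genes"] = hits
    return out


def compare_gain_frequency(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for gain counts k1/n1 vs k2/n2.

    Two-sided in the standard sense: the sum of hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed table's.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0 or k > n:
            raise ValueError("need 0 <= k <= n for both cohorts")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Whole-sample convenience pipeline and I/O


def call_sample(bins: pd.DataFrame, alpha: float = 0.01, n_perm: int = 1000,
                seed: int = 0, frac: float = 0.3,
                min_seg_delta: float = 0.1,
                ratio_threshold: float = GAIN_RATIO_THRESHOLD,
                focality_limit: float = FOCALITY_LIMIT_BP,
                genes: Optional[pd.DataFrame] = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> GC-corrected ratios -> segments -> classified events.

    Returns ``(profile, events)``: the per-bin table gains a ``ratio``
    column; events list one row per segment with chrom, bp interval,
    n_bins, mean_ratio, event_class and (if ``genes`` given) overlapping
    gene names.  Segmentation runs per chromosome; ratios stay normalized
    against the whole-genome mean.
    """
    profile = bins.copy()
    corrected = gc_correct(profile["count"].to_numpy(),
                           profile["gc"].to_numpy(), frac=frac)
    profile["ratio"] = normalize_to_genome_mean(corrected)

    rows = []
    for chrom, grp in profile.groupby("chrom", sort=True):
        segs = segment_cbs(grp["ratio"].to_numpy(), alpha=alpha,
                           n_perm=n_perm, seed=seed,
                           min_seg_delta=min_seg_delta)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for s in segs:
            rows.append((chrom, int(starts[s.start]), int(ends[s.end - 1]),
                         s.n_bins, s.mean))
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins",
                                           "mean_ratio"])
    events = call_focal_gains(segments, ratio_threshold=ratio_threshold,
                              focality_limit=focality_limit)
    if genes is not None:
        events = annotate_genes(events, genes)
    return profile, events


def write_seg(path, sample: str, segments: pd.DataFrame) -> None:
    """Write segments as a SEG file (1-based inclusive coordinates)."""
    out = pd.DataFrame({
        "ID": sample,
        "chrom": segments["chrom"],
        "loc.start": segments["start"] + 1,
        "loc.end": segments["end"],
        "num.mark": segments["n_bins"],
        "seg.mean": segments["mean_ratio"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_bins(path) -> pd.DataFrame:
    """Read a bin-count TSV (chrom, start, end, gc, count; half-open bp)."""
    bins = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gc", "count"}
    if not required <= set(bins.columns):
        raise ValueError(f"bin table needs columns {sorted(required)}")
    return bins
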