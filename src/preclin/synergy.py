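"""Bliss excess-over-independence synergy and z-score expression signatures.

Bliss independence predicts the combined fractional inhibition of two
non-interacting drugs as ``eA + eB - eA*eB``; the excess of the observed
combined inhibition over that expectation is the synergy score per dose
pair (positive = synergy), and the matrix mean over nonzero dose pairs is
the cell line's mean synergy.

Drug-perturbation signatures are per-gene standard scores of a treated
sample against its vehicle controls; signatures from several cell lines or
drugs are integrated into a consensus by Stouffer's method (sum of z over
sqrt(k)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlissResult",
    "SignatureVector",
    "bliss_excess",
    "zscore_signature",
    "consensus_signature",
]


@dataclass
class BlissResult:
    """Per-dose-pair Bliss excess and its matrix mean."""

    excess: pd.DataFrame      # nonzero drug-A doses x nonzero drug-B doses
    mean_synergy: float


def bliss_excess(matrix: pd.DataFrame) -> BlissResult:
    """Excess over Bliss independence for a dose-pair viability grid.

    ``matrix`` is viability (fraction of vehicle) indexed by drug-A dose
    (rows) and drug-B dose (columns), and must include the zero-dose row
    and column — the single-agent margins.  Viability is clipped to [0, 1]
    before conversion to inhibition (Bliss independence is defined for
    fractional effects).  Excess is symmetric under swapping the two drugs.
    """
    rows = matrix.index.to_numpy(dtype=float)
    cols = matrix.columns.to_numpy(dtype=float)
    if 0.0 not in rows or 0.0 not in cols:
        raise ValueError("matrix must include zero-dose single-agent margins")
    v = np.clip(matrix.to_numpy(dtype=float), 0.0, 1.0)
    e = 1.0 - v
    i0 = int(np.flatnonzero(rows == 0.0)[0])
    j0 = int(np.flatnonzero(cols == 0.0)[0])
    eA = e[:, j0]
    eB = e[i0, :]
    expected = eA[:, None] + eB[None, :] - eA[:, None] * eB[None, :]
    excess = e - expected
    nz_r = rows != 0.0
    nz_c = cols != 0.0
    block = pd.DataFrame(excess[np.ix_(nz_r, nz_c)],
                         index=pd.Index(rows[nz_r], name=matrix.index.name),
                         columns=pd.Index(cols[nz_c],
                                          name=matrix.columns.name))
    return BlissResult(excess=block, mean_synergy=float(
        block.to_numpy().mean()))


@dataclass
class SignatureVector:
    """Per-gene z-scores with a flag for zero-variance control genes."""

    z: pd.Series          # NaN where the control sd is zero
    zero_sd: pd.Series    # boolean, aligned with z


def zscore_signature(treated: pd.Series,
                     controls: pd.DataFrame) -> SignatureVector:
    """Standard score of a treated sample against vehicle controls.

    ``controls`` is genes x replicates (>= 2 replicates); z(g) =
    (x(g) - mean_ctrl(g)) / sd_ctrl(g) with the sample sd (ddof = 1).
    Genes whose controls have zero sd get z = NaN and are flagged.
    """
    if controls.shape[1] < 2:
        raise ValueError("need at least 2 control replicates")
    controls = controls.loc[treated.index]
    mean = controls.mean(axis=1)
    sd = controls.std(axis=1, ddof=1)
    zero = sd == 0
    z = (treated - mean) / sd.where(~zero)
    return SignatureVector(z=z, zero_sd=zero)


def consensus_signature(signatures: Sequence[SignatureVector | pd.Series],
                        method: str = "stouffer") -> pd.Series:
    """Integrate signatures over a shared gene universe.

    Per gene, Stouffer's combination z = sum(z_i) / sqrt(k) over the k
    signatures with defined (non-NaN) values for that gene; ``method=
    'mean'`` averages instead.  Genes come from the union of the inputs;
    an empty gene intersection raises.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    series = [s.z if isinstance(s, SignatureVector) else s
              for s in signatures]
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    if common.empty:
        raise ValueError("signatures share no genes")
    stacked = pd.concat(series, axis=1)
    k = stacked.notna().sum(axis=1)
    total = stacked.sum(axis=1, skipna=True)
    if method == "stouffer":
        out = total / np.sqrt(k.where(k > 0))
    elif method == "mean":
        out = total / k.where(k > 0)
    else:
        raise ValueError("method must be 'stouffer' or 'mean'")
    return out
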