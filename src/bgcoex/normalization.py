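"""Expression normalization: TPM and median-of-ratios size factors.

TPM (transcripts per million) divides each gene's count by its length in bp
and rescales each sample so the length-normalized rates sum to 10^6:

    TPM_gs = (c_gs / L_g) / sum_g' (c_g's / L_g') * 10^6

Median-of-ratios size factors capture per-sample sequencing depth for
between-sample comparisons: each gene with nonzero counts in every sample
gets a cross-sample geometric-mean reference, and a sample's factor is the
median over those genes of count / reference.  Factors are deliberately not
rescaled to geometric mean 1 — only factor ratios matter downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import CountMatrix


class NormalizationError(ValueError):
    """Raised when size factors are undefined for the given matrix."""


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million matrix (genes x samples).

    A sample with all-zero counts yields an all-zero TPM column rather than
    NaN.
    """
    rates = cm.counts.to_numpy(dtype=float) / cm.lengths.to_numpy(dtype=float)[:, None]
    colsum = rates.sum(axis=0)
    safe = np.where(colsum > 0, colsum, 1.0)
    tpm = rates / safe[None, :] * 1.0e6
    return pd.DataFrame(tpm, index=cm.counts.index, columns=cm.counts.columns)


def size_factors(cm: CountMatrix, pseudocount: bool = False) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Parameters
    ----------
    cm:
        Count matrix; at least one gene must have nonzero counts in every
        sample, otherwise the factors are undefined.
    pseudocount:
        Add 1 to every count first, making all genes usable.  Off by
        default; the error message suggests it when needed.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if pseudocount:
        counts = counts + 1.0
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined (consider pseudocount=True)"
        )
    sub = counts[usable]
    # geometric mean in log space for overflow safety
    reference = np.exp(np.log(sub).mean(axis=1))
    ratios = sub / reference[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.counts.columns, name="factor")
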