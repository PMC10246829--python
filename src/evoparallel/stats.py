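"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries are passed through.

    NaN p-values (e.g. non-converged fits) are excluded from the adjustment
    and stay NaN, so they never count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pairwise_pearson(mat: np.ndarray) -> np.ndarray:
    """Correlation matrix over the columns of ``mat`` (features x columns).

    Rows with a NaN in any column are dropped pairwise-complete is not
    needed here because every stage produces a common feature universe.
    """
    ok = ~np.isnan(mat).any(axis=1)
    return np.corrcoef(mat[ok].T)
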