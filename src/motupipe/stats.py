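"""Depth-stratification and correlation analytics.

Covers the depth-of-highest-abundance assignment per mOTU and its
cumulative attribution per sampled depth, Spearman rank correlations,
first-order partial correlations computed on the Spearman correlations
(r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), p from the
t approximation with n - 3 degrees of freedom), and top-N rank-abundance
overlap between depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    partial_rho: float | None = None
    controlled_variable: str | None = None

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("rho out of [-1, 1]")
        if self.partial_rho is not None and abs(self.partial_rho) > 1 + 1e-12:
            raise ValueError("partial rho out of [-1, 1]")


@dataclass
class DepthProfile:
    motu_id: str
    depth_means: pd.Series  # depth -> mean relative abundance
    peak_depth: float


def depth_means(
    rel_abundance: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """mOTU x depth matrix of mean relative abundance over each depth's
    time points."""
    m = metadata.set_index("sample_id")["depth"]
    groups = rel_abundance.T.groupby(m.reindex(rel_abundance.columns))
    return groups.mean().T


def depth_of_max(
    rel_abundance: pd.DataFrame, metadata: pd.DataFrame
) -> list[DepthProfile]:
    """Per mOTU, the depth of highest mean relative abundance.

    Depth means average each depth's time points; exact ties pick the
    shallowest depth.  mOTUs absent everywhere carry no peak and are
    excluded with a warning.
    """
    means = depth_means(rel_abundance, metadata)
    if means.shape[1] < 2:
        raise ValueError("need at least 2 depths")
    means = means[sorted(means.columns)]
    absent = means.index[(means <= 0).all(axis=1)]
    if len(absent):
        import warnings

        warnings.warn(
            f"{len(absent)} mOTUs absent at every depth have no peak depth"
        )
    out = []
    for motu in means.index.difference(absent, sort=False):
        row = means.loc[motu]
        peak = row.index[int(np.argmax(row.to_numpy()))]  # first = shallowest
        out.append(DepthProfile(motu_id=motu, depth_means=row, peak_depth=peak))
    return out


def depth_attribution(
    profiles: list[DepthProfile],
    rel_abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    subset: set | None = None,
) -> pd.DataFrame:
    """Cumulative abundance at each sampled depth attributed to each peak
    depth (peak depth rows x sampled depth columns).

    At every sampled depth, mOTU mean abundances are grouped by the mOTU's
    depth of highest abundance and summed; per-column sums equal the total
    included abundance at that depth.  ``subset`` optionally restricts to a
    set of mOTU ids (e.g. core or non-core).
    """
    means = depth_means(rel_abundance, metadata)
    depths = sorted(means.columns)
    rows = {}
    peak_of = {
        p.motu_id: p.peak_depth
        for p in profiles
        if subset is None or p.motu_id in subset
    }
    included = [m for m in means.index if m in peak_of]
    peaks = pd.Series({m: peak_of[m] for m in included})
    att = means.loc[included].groupby(peaks).sum()
    att = att.reindex(index=depths, columns=depths, fill_value=0.0)
    att.index.name = "peak_depth"
    att.columns.name = "sampled_depth"
    return att


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; p-value from
    the large-sample t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


def _spearman_rho(x, y) -> float:
    return float(sps.spearmanr(x, y)[0])


def partial_correlation(x, y, z, controlled_variable: str = "z") -> CorrelationResult:
    """First-order partial Spearman correlation of x and y given z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations for a partial correlation")
    r_xy = _spearman_rho(x, y)
    r_xz = _spearman_rho(x, z)
    r_yz = _spearman_rho(y, z)
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError(
            "degenerate partial correlation: a control correlation is +/-1"
        )
    partial = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    partial = float(np.clip(partial, -1.0, 1.0))
    df = n - 3
    if abs(partial) >= 1.0:
        p = 0.0
    else:
        t = partial * np.sqrt(df / (1 - partial**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        rho=r_xy,
        p_value=p,
        n=n,
        partial_rho=partial,
        controlled_variable=controlled_variable,
    )


def top_n_overlap(
    abund_a: pd.Series,
    abund_b: pd.Series,
    n: int,
    ids: pd.Index | None = None,
) -> tuple[int, bool]:
    """Overlap of the top-``n`` most abundant mOTUs of two depth profiles.

    ``ids`` optionally restricts both vectors to one clade's mOTUs.  Ties at
    rank n break toward the lexicographically smaller mOTU id; if fewer than
    n mOTUs are nonzero in a vector, all available are used and the second
    return value flags the shortfall.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ids is not None:
        abund_a = abund_a.loc[[i for i in ids if i in abund_a.index]]
        abund_b = abund_b.loc[[i for i in ids if i in abund_b.index]]

    def top(v: pd.Series) -> tuple[set, bool]:
        nz = v[v > 0]
        short = len(nz) < n
        # rank on (-abundance, id): ties at the boundary go to smaller ids
        ranked = nz.iloc[np.lexsort((nz.index.astype(str), -nz.to_numpy()))]
        return set(ranked.index[:n]), short

    ta, sa = top(abund_a)
    tb, sb = top(abund_b)
    return len(ta & tb), (sa or sb)
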