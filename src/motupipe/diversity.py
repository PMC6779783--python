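"""Rarefied richness, per-depth core-mOTU sets and clade summaries.

Richness comparisons across unevenly sequenced samples use a single
multivariate-hypergeometric down-sampling of each sample's uniquely mapped
insert counts to a common target (by default the dataset's minimum
per-sample total).  A core-mOTU at a depth is an mOTU present (rarefied
count >= 1) at every time point sampled at that depth; total richness at a
depth counts mOTUs present at any time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CoreSet:
    """Per-depth core populations and richness summaries."""

    core: dict  # depth -> set of motu ids
    core_richness: dict  # depth -> int
    total_richness: dict  # depth -> int
    core_abundance: dict = field(default_factory=dict)  # depth -> mean fraction

    @property
    def all_core_motus(self) -> set:
        out: set = set()
        for s in self.core.values():
            out |= s
        return out


def rarefy(counts, target: int, seed: int) -> np.ndarray:
    """Down-sample an integer count vector to exactly ``target`` total,
    without replacement (multivariate hypergeometric).  Deterministic given
    ``seed``."""
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    arr = arr.astype(np.int64)
    total = int(arr.sum())
    if total < target:
        raise ValueError(
            f"cannot rarefy a sample with {total} inserts to {target}"
        )
    if total == target:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, target)


def rarefy_matrix(
    counts: pd.DataFrame,
    target: int | str = "auto",
    seed: int = 42,
) -> pd.DataFrame:
    """Rarefy every sample column of an mOTU x sample integer matrix.

    ``target='auto'`` uses the minimum per-sample total (the convention for
    a fixed dataset); each sample gets an independent, seed-derived
    substream so results do not depend on column order processing.
    """
    totals = counts.sum(axis=0)
    if target == "auto":
        target = int(totals.min())
    short = totals[totals < target]
    if len(short):
        raise ValueError(
            f"samples below the rarefaction target {target}: "
            f"{short.index.tolist()}"
        )
    cols = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(counts.columns))
    for col, child in zip(counts.columns, children):
        rng = np.random.default_rng(child)
        arr = counts[col].to_numpy().astype(np.int64)
        if arr.sum() == target:
            cols[col] = arr
        else:
            cols[col] = rng.multivariate_hypergeometric(arr, int(target))
    out = pd.DataFrame(cols, index=counts.index)
    out.index.name = counts.index.name
    return out


def richness(counts) -> int:
    """Number of mOTUs present (count >= 1)."""
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return int((arr >= 1).sum())


def core_motus(depth_samples: pd.DataFrame) -> set:
    """Exact intersection of per-sample presence sets (columns = samples at
    one depth)."""
    if depth_samples.shape[1] < 1:
        raise ValueError("need at least one sample at the depth")
    present = depth_samples >= 1
    mask = present.all(axis=1)
    return set(depth_samples.index[mask])


def total_richness(depth_samples: pd.DataFrame) -> int:
    """Size of the union of per-sample presence sets."""
    if depth_samples.shape[1] < 1:
        raise ValueError("need at least one sample at the depth")
    return int(((depth_samples >= 1).any(axis=1)).sum())


def core_abundance_fraction(
    core: set,
    rel_abundance: pd.DataFrame,
    sample_ids,
) -> float:
    """Mean over the depth's samples of the summed relative abundance of
    the core mOTUs."""
    core_idx = [m for m in rel_abundance.index if m in core]
    if not core_idx:
        return 0.0
    return float(rel_abundance.loc[core_idx, list(sample_ids)].sum(axis=0).mean())


def core_set(
    rarefied: pd.DataFrame,
    metadata: pd.DataFrame,
    rel_abundance: pd.DataFrame | None = None,
) -> CoreSet:
    """Per-depth core sets, core/total richness and mean core abundance.

    ``rarefied`` is the rarefied unique-count matrix (mOTU x sample);
    ``metadata`` maps sample_id -> depth; ``rel_abundance`` (optional) is
    used for the mean core abundance fraction per depth.
    """
    core, core_r, total_r, core_ab = {}, {}, {}, {}
    for depth, sub in metadata.groupby("depth", sort=True):
        samples = [s for s in sub["sample_id"] if s in rarefied.columns]
        block = rarefied[samples]
        c = core_motus(block)
        core[depth] = c
        core_r[depth] = len(c)
        total_r[depth] = total_richness(block)
        if rel_abundance is not None:
            core_ab[depth] = core_abundance_fraction(c, rel_abundance, samples)
    return CoreSet(core=core, core_richness=core_r, total_richness=total_r, core_abundance=core_ab)


def clade_summaries(
    core: CoreSet,
    clades: pd.Series,
    rel_abundance: pd.DataFrame,
    rarefied: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-depth, per-clade richness and abundance summary.

    For every (depth, clade): total richness and core richness restricted to
    the clade's mOTUs, the mean (over the depth's samples) summed relative
    abundance of the clade, and the mean summed abundance of its core
    mOTUs.  Clades absent at a depth appear with zeros.
    """
    clades = clades.reindex(rarefied.index).fillna("unannotated")
    rows = []
    all_clades = sorted(clades.unique())
    for depth, sub in metadata.groupby("depth", sort=True):
        samples = [s for s in sub["sample_id"] if s in rarefied.columns]
        block = rarefied[samples]
        core_ids = core.core.get(depth, set())
        for clade in all_clades:
            ids = clades.index[clades == clade]
            cblock = block.loc[ids]
            c_core = core_ids & set(ids)
            mean_ab = float(
                rel_abundance.loc[ids, samples].sum(axis=0).mean()
            )
            mean_core_ab = (
                float(
                    rel_abundance.loc[sorted(c_core), samples].sum(axis=0).mean()
                )
                if c_core
                else 0.0
            )
            rows.append(
                {
                    "depth": depth,
                    "clade": clade,
                    "total_richness": total_richness(cblock)
                    if len(cblock)
                    else 0,
                    "core_richness": len(c_core),
                    "mean_abundance": mean_ab,
                    "mean_core_abundance": mean_core_ab,
                }
            )
    return pd.DataFrame(rows)
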