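"""Meta-analytic term decoding along the dominant gradient.

The gradient is sliced into 10 rank-based (equal-count) percentile bins;
each term's z-statistic map is averaged within every bin, giving a
term x 10 profile. Terms whose best bin mean exceeds the z threshold
(strictly) are retained and ordered by the positive-part centre of mass of
their profile — the staircase layout used to read a gradient's behavioural
spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TermDecodingProfile", "bin_gradient", "decode_terms"]

N_BINS = 10


@dataclass
class TermDecodingProfile:
    term_names: list[str]
    bin_edges: np.ndarray  # 11 gradient values delimiting the bins
    profile: np.ndarray  # term x 10 mean z per bin
    retained: np.ndarray  # bool per term
    term_order: np.ndarray  # centre-of-mass order statistic per term (NaN if unordered)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.profile, index=self.term_names,
            columns=[f"bin_{b}" for b in range(1, N_BINS + 1)],
        )
        df.insert(0, "term", self.term_names)
        df["retained"] = self.retained
        df["order"] = self.term_order
        return df.reset_index(drop=True)


def bin_gradient(gradient) -> np.ndarray:
    """Split voxels into 10 equal-count bins by ascending gradient rank.

    Returns a (10, n_voxels) boolean mask array partitioning the seed; ties
    in the gradient are broken by voxel id, and bin sizes differ by at most
    one voxel. Fewer than 10 voxels is an error.
    """
    g = np.asarray(gradient, dtype=np.float64)
    n = g.size
    if n < N_BINS:
        raise ValueError(f"need at least {N_BINS} voxels, got {n}")
    order = np.lexsort((np.arange(n), g))  # ascending value, id breaks ties
    masks = np.zeros((N_BINS, n), dtype=bool)
    for b, chunk in enumerate(np.array_split(order, N_BINS)):
        masks[b, chunk] = True
    return masks


def bin_edges(gradient, masks) -> np.ndarray:
    """11 gradient values delimiting the bins (min, 9 boundaries, max)."""
    g = np.asarray(gradient, dtype=np.float64)
    edges = [float(g.min())]
    for b in range(N_BINS - 1):
        edges.append(float(g[masks[b]].max()))
    edges.append(float(g.max()))
    return np.asarray(edges)


def decode_terms(masks, term_maps: dict, z_threshold: float = 2.3,
                 gradient=None) -> TermDecodingProfile:
    """Profile term z-maps over the gradient bins and filter by threshold.

    ``term_maps`` maps term name -> per-voxel z values on the seed grid.
    profile(t, b) is the mean z of term t in bin b (NaNs excluded with a
    warning; all-NaN terms are dropped). A term is retained when its maximum
    bin mean exceeds ``z_threshold`` strictly. The order statistic is
    sum_b b*max(profile, 0) / sum_b max(profile, 0) with b = 1..10.
    """
    names, profiles = [], []
    n_vox = masks.shape[1]
    for name, zmap in term_maps.items():
        z = np.asarray(zmap, dtype=np.float64)
        if z.shape != (n_vox,):
            raise ValueError(f"term {name!r} map not on the seed grid")
        if np.isnan(z).all():
            warnings.warn(f"term {name!r} is all-NaN on the seed; dropped", stacklevel=2)
            continue
        if np.isnan(z).any():
            warnings.warn(f"term {name!r} has NaNs on the seed; excluded from means",
                          stacklevel=2)
        prof = np.array([np.nanmean(z[masks[b]]) for b in range(N_BINS)])
        names.append(name)
        profiles.append(prof)
    profile = np.asarray(profiles) if profiles else np.empty((0, N_BINS))
    retained = (
        profile.max(axis=1) > z_threshold if len(names) else np.zeros(0, dtype=bool)
    )
    pos = np.maximum(profile, 0.0)
    bins = np.arange(1, N_BINS + 1)
    denom = pos.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        order = np.where(denom > 0, (pos * bins).sum(axis=1) / denom, np.nan)
    edges = (
        bin_edges(gradient, masks) if gradient is not None else np.full(N_BINS + 1, np.nan)
    )
    return TermDecodingProfile(
        term_names=names,
        bin_edges=edges,
        profile=profile,
        retained=retained,
        term_order=order,
    )
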