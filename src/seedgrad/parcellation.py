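"""Winner-take-all assignment of seed voxels to canonical networks.

Each seed voxel is correlated with the mean time course of every labeled
network (computed over target voxels only, so a voxel is never correlated
with a mean containing itself) and assigned to the best-correlated one.
Subdivisions are then summarized along the dominant gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GroupTimeSeries

__all__ = ["ParcellationResult", "network_mean_timecourses", "winner_take_all"]

UNASSIGNED = "unassigned"


@dataclass
class ParcellationResult:
    assignment: np.ndarray  # per seed voxel: network name or 'unassigned'
    correlations: np.ndarray  # seed voxel x network Pearson r
    network_names: list[str]
    subdivision_summary: pd.DataFrame  # network, n_voxels, mean_gradient, sd, rank


def network_mean_timecourses(targets: GroupTimeSeries, labels) -> tuple[np.ndarray, list[str]]:
    """Unweighted mean standardized series per network over its target voxels.

    ``labels`` is a per-target-voxel network id (name or integer); order of
    the returned rows follows first appearance sorted by label. Empty
    networks raise.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != targets.n_voxels:
        raise ValueError("one label required per target voxel")
    names = [str(x) for x in np.unique(labels)]
    means = np.empty((len(names), targets.n_timepoints))
    for i, name in enumerate(np.unique(labels)):
        sel = labels == name
        if not sel.any():
            raise ValueError(f"network {name!r} has no voxels")
        means[i] = targets.values[sel].mean(axis=0)
    return means, names


def winner_take_all(
    seed: GroupTimeSeries,
    network_means: np.ndarray,
    network_names: list[str],
    gradient,
) -> ParcellationResult:
    """Assign each seed voxel to its best-correlated network; summarize the gradient.

    Ties at the maximum correlation go to the lowest network index with a
    warning. Zero-variance voxels are labeled 'unassigned' and excluded from
    summaries. The subdivision summary is sorted by mean dominant-gradient
    value; networks with no voxels appear with n_voxels = 0.
    """
    if seed.n_timepoints != network_means.shape[1]:
        raise ValueError("seed series and network means must share time length")
    gradient = np.asarray(gradient, dtype=np.float64)

    def _std_rows(x):
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(xc, axis=1, keepdims=True)
        flat = norm[:, 0] == 0
        norm[flat] = 1.0
        z = xc / norm
        z[flat] = 0.0
        return z, flat

    s, flat_seed = _std_rows(seed.values)
    m, flat_net = _std_rows(network_means)
    if flat_net.any():
        raise ValueError("constant network mean time course")
    corr = s @ m.T
    best = np.argmax(corr, axis=1)
    ties = (corr == corr[np.arange(corr.shape[0]), best][:, None]).sum(axis=1) > 1
    if ties[~flat_seed].any():
        warnings.warn(
            f"{int(ties[~flat_seed].sum())} voxel(s) tie at maximum correlation; "
            "assigned to the lowest network index",
            stacklevel=2,
        )
    assignment = np.asarray([network_names[b] for b in best], dtype=object)
    if flat_seed.any():
        warnings.warn(
            f"{int(flat_seed.sum())} zero-variance seed voxel(s) left unassigned",
            stacklevel=2,
        )
        assignment[flat_seed] = UNASSIGNED

    rows = []
    for name in network_names:
        sel = assignment == name
        n = int(sel.sum())
        if n:
            vals = gradient[sel]
            rows.append((name, n, float(vals.mean()), float(vals.std(ddof=0))))
        else:
            rows.append((name, 0, np.nan, np.nan))
    summary = pd.DataFrame(rows, columns=["network", "n_voxels", "mean_gradient", "sd"])
    summary = summary.sort_values(
        "mean_gradient", na_position="last", kind="stable"
    ).reset_index(drop=True)
    summary["rank"] = np.where(
        summary["mean_gradient"].notna(), np.arange(1, len(summary) + 1), np.nan
    )
    return ParcellationResult(
        assignment=assignment,
        correlations=corr,
        network_names=list(network_names),
        subdivision_summary=summary,
    )
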