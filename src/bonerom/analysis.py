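"""Sensitivity and mass-change diagnostics over a snapshot campaign.

For each periprosthetic zone the response variable is the percentage mass
change between the initial and final density fields (element-centre density
times element volume, summed over the zone).  Global sensitivity of that
response to each pose parameter is measured with Spearman's rank
correlation, which captures monotone nonlinear dependence; tied observations
receive average ranks.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import SimplexMesh, RegionMap, element_volumes

__all__ = [
    "spearman",
    "mass_change_by_region",
    "sensitivity_campaign",
    "plot_mass_change",
    "plot_sensitivity",
]


def spearman(x, y) -> float:
    """Spearman's rank correlation ``rho = cov(R(Y), R(X)) / (s_RX s_RY)``.

    Ties are handled with average ranks.  A constant input makes the
    coefficient undefined; NaN is returned (never a silent zero).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples with at least 3 entries")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    cov = np.mean((rx - rx.mean()) * (ry - ry.mean()))
    return float(cov / (sx * sy))


def _element_center_density(mesh: SimplexMesh, phi_nodal: np.ndarray,
                            elems: np.ndarray) -> np.ndarray:
    return phi_nodal[mesh.elements[elems]].mean(axis=1)


def mass_change_by_region(
    mesh: SimplexMesh,
    regions: RegionMap,
    phi_init: np.ndarray,
    phi_final: np.ndarray,
) -> Dict[int, float]:
    """Percent mass change per zone.

    Element mass = element-centre density (mean of the vertex values of the
    nodal field) times element volume.  A zone with zero initial mass yields
    NaN rather than a spurious number.
    """
    regions.validate(mesh)
    vols = np.abs(element_volumes(mesh))
    out = {}
    for r, elems in regions.regions.items():
        v = vols[elems]
        m0 = float(np.sum(_element_center_density(mesh, phi_init, elems) * v))
        m1 = float(np.sum(_element_center_density(mesh, phi_final, elems) * v))
        out[r] = 100.0 * (m1 - m0) / m0 if m0 != 0 else float("nan")
    return out


def sensitivity_campaign(
    snapshot_set,
    mesh: SimplexMesh,
    regions: RegionMap,
    phi_init: np.ndarray,
):
    """Spearman sensitivity table plus mass-change summary statistics.

    For every (pose parameter, zone) pair the coefficient correlates the
    parameter column of ``P`` with the zone's percent mass change across all
    snapshots; an ``all`` column uses the whole bone domain.  Returns
    ``(table, summary)``: the table is parameters x (zones + "all"), the
    summary holds median/min/max mass change per zone.
    """
    S, P = snapshot_set.S, snapshot_set.P
    if S.shape[1] < 3:
        raise ValueError("need at least 3 snapshots for a sensitivity analysis")
    names = snapshot_set.param_names or [f"p{i}" for i in range(P.shape[0])]
    n_s = S.shape[1]
    responses = {r: np.empty(n_s) for r in regions.regions}
    responses["all"] = np.empty(n_s)
    all_map = RegionMap(regions={0: mesh.bone_elements})
    for j in range(n_s):
        per_region = mass_change_by_region(mesh, regions, phi_init, S[:, j])
        for r, v in per_region.items():
            responses[r][j] = v
        responses["all"][j] = mass_change_by_region(
            mesh, all_map, phi_init, S[:, j])[0]
    table = pd.DataFrame(
        {col: [spearman(P[i], resp) for i in range(P.shape[0])]
         for col, resp in responses.items()},
        index=names,
    )
    summary = pd.DataFrame(
        {
            "median": [float(np.median(responses[r])) for r in regions.regions],
            "min": [float(np.min(responses[r])) for r in regions.regions],
            "max": [float(np.max(responses[r])) for r in regions.regions],
        },
        index=list(regions.regions),
    )
    return table, summary


def plot_mass_change(summary, ax=None):
    """Bar chart of median zone mass change with min/max whiskers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summary))
    med = summary["median"].to_numpy()
    err = np.vstack([med - summary["min"], summary["max"] - med])
    ax.bar(x, med, yerr=err, capsize=3, color="tab:gray")
    ax.set_xticks(x, [str(r) for r in summary.index])
    ax.set_xlabel("zone")
    ax.set_ylabel("mass change [%]")
    ax.axhline(0.0, color="k", lw=0.5)
    return ax


def plot_sensitivity(table, column="all", ax=None):
    """Bar chart of Spearman coefficients for one zone (or the whole bone)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = table[column].to_numpy()
    x = np.arange(len(table))
    ax.bar(x, vals, color="tab:blue")
    ax.set_xticks(x, list(table.index))
    ax.set_ylim(-1.05, 1.05)
    ax.set_ylabel(f"Spearman rho ({column})")
    ax.axhline(0.0, color="k", lw=0.5)
    return ax
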