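"""Villeger functional diversity indices on the PCoA trait space.

Per plot (assemblage): FRic is the convex-hull volume of the member species
in the retained axes (dimensionality reduced to min(4, S-1) for small
assemblages, via the subset's own principal axes); FEve is the regularity of
abundance along the minimum spanning tree,
``FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))`` with
``PEW_l = EW_l / sum EW`` and ``EW_l = d(i,j) / (w_i + w_j)``; FDiv measures
abundance weighting of extreme trait values relative to the centroid of the
hull vertices, ``FDiv = (Dd + dbarG) / (D|d| + dbarG)``.  Community trait
position is summarized by abundance-weighted mean PC scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform


def _reduce_dims(coords: np.ndarray, max_dim: int) -> np.ndarray:
    """Project a point set onto its own top principal axes if overdimensioned."""
    n, d = coords.shape
    target = min(max_dim, n - 1)
    if d <= target:
        return coords
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:target].T


def hull_volume(coords: np.ndarray) -> float:
    """Convex-hull volume in min(d, n-1) dimensions; length when 1-D."""
    pts = _reduce_dims(np.asarray(coords, float), coords.shape[1])
    if pts.shape[1] == 1:
        return float(np.ptp(pts))
    hull = ConvexHull(pts)
    return float(hull.volume)


def functional_evenness(coords: np.ndarray, weights: np.ndarray) -> float:
    """Abundance-weighted MST regularity, in [0, 1]."""
    S = coords.shape[0]
    if S < 3:
        raise ValueError("FEve needs at least 3 species")
    w = weights / weights.sum()
    D = squareform(pdist(coords))
    mst = minimum_spanning_tree(D).tocoo()
    ew = np.array([D[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    if ew.sum() == 0:
        return 1.0  # all species coincide: perfectly regular, degenerate
    pew = ew / ew.sum()
    s1 = 1.0 / (S - 1)
    return float((np.minimum(pew, s1).sum() - s1) / (1.0 - s1))


def functional_divergence(coords: np.ndarray, weights: np.ndarray) -> float:
    """Abundance-weighted divergence from the hull-vertex centroid, in [0, 1]."""
    S = coords.shape[0]
    if S < 3:
        raise ValueError("FDiv needs at least 3 species")
    pts = _reduce_dims(np.asarray(coords, float), coords.shape[1])
    w = weights / weights.sum()
    if pts.shape[1] == 1:
        verts = np.array([np.argmin(pts[:, 0]), np.argmax(pts[:, 0])])
    else:
        verts = ConvexHull(pts).vertices
    centroid = pts[verts].mean(axis=0)
    dg = np.linalg.norm(pts - centroid, axis=1)
    dbar = dg.mean()
    dd = float((w * (dg - dbar)).sum())
    dabs = float((w * np.abs(dg - dbar)).sum())
    denom = dabs + dbar
    if denom == 0:
        raise ValueError("degenerate assemblage: all species at the centroid")
    return float((dd + dbar) / denom)


@dataclass
class FDResult:
    """Per-plot functional diversity table with missing-value reasons."""

    table: pd.DataFrame
    notes: dict


def fd_metrics(space, abundance, n_axes: int = 4) -> FDResult:
    """FRic/FEve/FDiv and community-weighted PC means for every plot.

    Parameters
    ----------
    space
        A :class:`~strataves.traitspace.FunctionalSpace` (or anything with a
        species-indexed ``coords`` frame).
    abundance
        An :class:`~strataves.distance_sampling.AbundanceMatrix` or a plain
        plot x species weight frame; species with positive weight are the
        assemblage members, the weights enter FEve/FDiv and the PC means.
    """
    weights_df = abundance.nhat if hasattr(abundance, "nhat") else abundance
    coords = space.coords.iloc[:, :n_axes]
    pc_cols = list(coords.columns)
    rows = {}
    notes = {}
    for plot, row in weights_df.iterrows():
        members = row.index[(row.values > 0)]
        members = members.intersection(coords.index)
        S = members.size
        rec = {"SpRich": S, "FRich": np.nan, "FEven": np.nan, "FDiv": np.nan}
        rec.update({c: np.nan for c in pc_cols})
        if S == 0:
            notes[plot] = "empty assemblage"
            rows[plot] = rec
            continue
        w = row.loc[members].values.astype(float)
        pts = coords.loc[members].values
        wn = w / w.sum()
        for c, v in zip(pc_cols, wn @ pts):
            rec[c] = float(v)
        if S < 2:
            notes[plot] = "fewer than 2 species: FD undefined"
        else:
            try:
                rec["FRich"] = hull_volume(pts)
            except QhullError:
                notes[plot] = "degenerate hull"
            if S >= 3:
                try:
                    rec["FEven"] = functional_evenness(pts, w)
                    rec["FDiv"] = functional_divergence(pts, w)
                except (QhullError, ValueError) as exc:
                    notes.setdefault(plot, str(exc))
            else:
                notes.setdefault(plot, "fewer than 3 species: FEve/FDiv undefined")
        rows[plot] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = weights_df.index.name or "plot"
    return FDResult(table=table, notes=notes)
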