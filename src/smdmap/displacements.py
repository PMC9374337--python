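"""Frame pairing and peak pairing: localizations -> displacements.

Stroboscopic acquisition places one laser pulse at the end of an odd frame
and one at the beginning of the next even frame, so an emitter is seen
twice, a fixed lag apart, in one *frame couple*. Displacements are obtained
by matching every peak in the first frame of a couple with **all** peaks
within a maximum radius in the second frame; ambiguous matches are kept
deliberately, because the linear ``k*r`` term of the displacement density
models exactly those misassignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_R_MAX = 600.0

__all__ = [
    "FrameCouple",
    "pair_frames",
    "pair_peaks",
    "extract_displacements",
    "filter_displacements",
]


@dataclass
class FrameCouple:
    """One stroboscopic frame pair: all localizations of the two frames."""

    index: int
    first_frame: int
    first: pd.DataFrame
    second: pd.DataFrame


def pair_frames(localizations: pd.DataFrame, phase: int = 0) -> list[FrameCouple]:
    """Group localizations into disjoint consecutive frame couples.

    ``phase=0`` pairs frames (0,1), (2,3), ...; ``phase=1`` pairs
    (1,2), (3,4), ... leaving frame 0 (and possibly the last frame)
    unpaired. Every localization belongs to at most one couple.
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    if localizations.empty:
        return []
    by_frame = dict(tuple(localizations.groupby("frame", sort=True)))
    empty = localizations.iloc[0:0]
    max_frame = int(localizations["frame"].max())
    couples = []
    index = 0
    for f in range(phase, max_frame, 2):
        first = by_frame.get(f)
        second = by_frame.get(f + 1)
        if first is None and second is None:
            index += 1
            continue
        couples.append(
            FrameCouple(
                index=index,
                first_frame=f,
                first=first if first is not None else empty,
                second=second if second is not None else empty,
            )
        )
        index += 1
    return couples


def pair_peaks(couple: FrameCouple, r_max: float = DEFAULT_R_MAX) -> pd.DataFrame:
    """All-pairs peak matching within ``r_max`` for one frame couple.

    Every (first-frame, second-frame) pair of peaks with planar distance
    ``<= r_max`` yields one displacement anchored at the first-frame
    position. No deduplication or mutual-nearest selection is performed.

    Returns a DataFrame with columns ``origin_x_nm``, ``origin_y_nm``,
    ``end_x_nm``, ``end_y_nm``, ``r_nm``, ``couple``; when both frames
    carry a ``truth_id`` column it is propagated as ``truth_first`` /
    ``truth_second`` so generators can be validated against their labels.
    """
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    cols = [
        "origin_x_nm", "origin_y_nm", "end_x_nm", "end_y_nm", "r_nm", "couple",
    ]
    if couple.first.empty or couple.second.empty:
        return pd.DataFrame(columns=cols)
    a = couple.first[["x_nm", "y_nm"]].to_numpy(float)
    b = couple.second[["x_nm", "y_nm"]].to_numpy(float)
    pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=r_max)
    ii = np.repeat(np.arange(len(a)), [len(p) for p in pairs])
    if len(ii) == 0:
        return pd.DataFrame(columns=cols)
    jj = np.concatenate([np.sort(np.asarray(p, dtype=int)) for p in pairs])
    delta = b[jj] - a[ii]
    out = pd.DataFrame(
        {
            "origin_x_nm": a[ii, 0],
            "origin_y_nm": a[ii, 1],
            "end_x_nm": b[jj, 0],
            "end_y_nm": b[jj, 1],
            "r_nm": np.sqrt((delta**2).sum(axis=1)),
            "couple": couple.index,
        }
    )
    if "truth_id" in couple.first.columns and "truth_id" in couple.second.columns:
        out["truth_first"] = couple.first["truth_id"].to_numpy()[ii]
        out["truth_second"] = couple.second["truth_id"].to_numpy()[jj]
    return out


def extract_displacements(
    localizations: pd.DataFrame,
    phase: int = 0,
    r_max: float = DEFAULT_R_MAX,
) -> pd.DataFrame:
    """Full pairing chain: frame couples, all-pairs matching, concatenation."""
    couples = pair_frames(localizations, phase=phase)
    parts = [pair_peaks(c, r_max=r_max) for c in couples]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pair_peaks(FrameCouple(0, 0, localizations.iloc[0:0], localizations.iloc[0:0]))
    out = pd.concat(parts, ignore_index=True)
    if "dt" in localizations.attrs:
        out.attrs["dt"] = localizations.attrs["dt"]
    return out


def filter_displacements(displacements: pd.DataFrame, r_max: float = DEFAULT_R_MAX) -> pd.DataFrame:
    """Keep displacements with ``r <= r_max`` (boundary inclusive).

    The same bound must be used as the normalization limit of the fitted
    density.
    """
    out = displacements.loc[displacements["r_nm"] <= r_max].reset_index(drop=True)
    out.attrs.update(displacements.attrs)
    return out
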