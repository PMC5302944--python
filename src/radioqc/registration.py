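"""Detector-to-cell-layer registration and track-focus pairing.

Between the FNTD read-out and the cell-layer imaging the nuclei move by a
few micrometres; the movement is modelled as one rigid translation per field
(no rotation or scaling).  The translation is estimated robustly as the
component-wise median of nearest-neighbour displacement vectors, re-matching
once after applying the current estimate.  Primary tracks are then paired
one-to-one with foci by greedy nearest-neighbour assignment in ascending
separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TranslationEstimate",
    "TrackFocusPair",
    "estimate_translation",
    "match_tracks_to_foci",
]


@dataclass(frozen=True)
class TranslationEstimate:
    """A rigid (dx, dy) translation in um with robustness diagnostics."""

    dx: float
    dy: float
    n_inliers: int
    residual_spread: float  # median residual after registration, um
    reliable: bool

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx, self.dy])


@dataclass(frozen=True)
class TrackFocusPair:
    spot_index: int
    focus_index: int
    separation: float  # um, after translation


def _as_xy(objs) -> np.ndarray:
    """Coerce spot/focus objects or arrays to an (n, 2) um coordinate array."""
    arr = np.asarray(objs, dtype=object)
    if arr.dtype != object:
        out = np.asarray(objs, dtype=float)
        return out.reshape(-1, 2)
    try:
        out = np.asarray(objs, dtype=float)
        return out.reshape(-1, 2)
    except (TypeError, ValueError):
        pass
    pts = []
    for o in objs:
        if hasattr(o, "x") and hasattr(o, "y"):
            pts.append((o.x, o.y))
        elif hasattr(o, "position"):
            pts.append(tuple(o.position))
        else:
            raise TypeError(f"cannot extract coordinates from {type(o)!r}")
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def _coarse_shift(sp: np.ndarray, fo: np.ndarray, max_search: float, bin_um: float = 0.5):
    """Mode of the pairwise displacement histogram within max_search.

    Every true track-focus pair votes for the same displacement while
    unrelated pairs spread smoothly, so the mode localises the translation
    even when most tracks have no focus (dense detector plane, sparse foci).
    """
    tree_sp = cKDTree(sp)
    votes = []
    for j, f in enumerate(fo):
        for i in tree_sp.query_ball_point(f, max_search):
            votes.append(f - sp[i])
    if len(votes) < 5:
        raise ValueError("fewer than 5 candidate displacement pairs within max_search")
    votes = np.asarray(votes)
    n_bins = max(int(np.ceil(2 * max_search / bin_um)), 1)
    hist, xe, ye = np.histogram2d(
        votes[:, 0], votes[:, 1],
        bins=n_bins, range=[[-max_search, max_search]] * 2,
    )
    ix, iy = np.unravel_index(np.argmax(hist), hist.shape)
    return np.array([0.5 * (xe[ix] + xe[ix + 1]), 0.5 * (ye[iy] + ye[iy + 1])])


def estimate_translation(
    spots, foci, max_search: float = 10.0, n_iter: int = 2
) -> TranslationEstimate:
    """Estimate the global spot-to-focus translation (um).

    A coarse estimate is taken as the mode of the pairwise displacement
    histogram within ``max_search`` (robust even when most tracks produce no
    focus), then refined by the component-wise median of nearest-neighbour
    displacement vectors in a narrow window, iterated ``n_iter`` times with
    re-matching, and finally by the mean over inliers (residual within 3x
    the median absolute residual; the trimmed mean is statistically more
    efficient than the median once outliers are excluded).  The estimate is
    flagged unreliable when fewer than half the matched spots are inliers or
    the residual spread approaches the search radius (foci unrelated to the
    tracks).
    """
    sp = _as_xy(spots)
    fo = _as_xy(foci)
    if len(sp) < 5 or len(fo) < 5:
        raise ValueError("need >= 5 spots and >= 5 foci to estimate a translation")
    tree = cKDTree(fo)
    shift = _coarse_shift(sp, fo, max_search)
    refine_radius = min(max_search, 1.5)
    disp = None
    for _ in range(max(n_iter, 1)):
        moved = sp + shift
        dist, idx = tree.query(moved, distance_upper_bound=refine_radius)
        ok = np.isfinite(dist)
        if ok.sum() < 5:  # fall back to the full search radius
            dist, idx = tree.query(moved, distance_upper_bound=max_search)
            ok = np.isfinite(dist)
        if ok.sum() < 5:
            raise ValueError("fewer than 5 candidate displacement pairs within max_search")
        disp = fo[idx[ok]] - moved[ok]
        shift = shift + np.median(disp, axis=0)
    # trimmed-mean refinement over inliers of the median solution
    moved = sp + shift
    dist, idx = tree.query(moved, distance_upper_bound=refine_radius)
    ok = np.isfinite(dist)
    if ok.sum() >= 5:
        disp = fo[idx[ok]] - moved[ok]
        resid = np.linalg.norm(disp, axis=1)
        med_resid = np.median(resid)
        inl = resid <= 3.0 * max(med_resid, 1e-12)
        if inl.sum() >= 5:
            shift = shift + disp[inl].mean(axis=0)
    moved = sp + shift
    dist, idx = tree.query(moved, distance_upper_bound=refine_radius)
    ok = np.isfinite(dist)
    if ok.sum() < 5:
        dist, idx = tree.query(moved, distance_upper_bound=max_search)
        ok = np.isfinite(dist)
    resid = dist[ok]
    med = float(np.median(resid)) if resid.size else np.inf
    inliers = int((resid <= 3.0 * max(med, 1e-12)).sum()) if resid.size else 0
    reliable = bool(
        resid.size >= 5 and inliers >= 0.5 * ok.sum() and med < 0.3 * max_search
    )
    return TranslationEstimate(
        dx=float(shift[0]),
        dy=float(shift[1]),
        n_inliers=inliers,
        residual_spread=med,
        reliable=reliable,
    )


def match_tracks_to_foci(
    spots,
    foci,
    translation: TranslationEstimate | Sequence[float],
    max_match_distance: float = 5.0,
) -> tuple[list[TrackFocusPair], list[int], list[int]]:
    """One-to-one greedy pairing of translated spots with foci.

    Candidate pairs within ``max_match_distance`` um are accepted in
    ascending separation, each spot and focus at most once.  Returns
    ``(pairs, unmatched_spot_indices, unmatched_focus_indices)``.  The
    default search radius allows for the ~3 um nuclear movement plus
    focus-position uncertainty.
    """
    sp = _as_xy(spots)
    fo = _as_xy(foci)
    if isinstance(translation, TranslationEstimate):
        t = translation.vector
    else:
        t = np.asarray(translation, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("translation must be finite")
    pairs: list[TrackFocusPair] = []
    if len(sp) == 0 or len(fo) == 0 or max_match_distance <= 0:
        return pairs, list(range(len(sp))), list(range(len(fo)))
    moved = sp + t
    tree = cKDTree(fo)
    candidates = []
    for i, p in enumerate(moved):
        for j in tree.query_ball_point(p, max_match_distance):
            candidates.append((float(np.linalg.norm(fo[j] - p)), i, j))
    candidates.sort()
    used_s: set[int] = set()
    used_f: set[int] = set()
    for d, i, j in candidates:
        if i in used_s or j in used_f:
            continue
        used_s.add(i)
        used_f.add(j)
        pairs.append(TrackFocusPair(spot_index=i, focus_index=j, separation=d))
    unmatched_s = [i for i in range(len(sp)) if i not in used_s]
    unmatched_f = [j for j in range(len(fo)) if j not in used_f]
    return pairs, unmatched_s, unmatched_f
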