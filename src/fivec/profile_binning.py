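"""Anchor-averaged interaction profiles, sliding-window binning and contact calling.

An anchored 5C design reads out one row of the contact matrix per reverse
"bait" primer: the interaction frequency of the promoter with every forward
fragment.  The profile of a library is the arithmetic mean of its anchors'
rows, indexed by forward-fragment midpoint.  Profiles are smoothed with
sliding windows (default 80 kb advancing by 1/6 of the window — overlapping
bins average out per-contact noise); a window containing no fragments is
*missing*, never zero.

Strong contacts are called against a log-log linear distance-decay fit:
log(value) regressed on log(distance to anchor); the score of a bin is its
residual divided by a robust (MAD) scale, and runs of bins at or above the
z threshold are merged into ranked regions.  Bins overlapping the anchors
themselves are excluded — the self-neighbourhood is dominated by trivial
proximity ligation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomicInterval, LocusSpec, RestrictionFragment, signed_tss_distance
from .junction_quant import IFL
from .normalization import NormalizedIFL
from .primer_design import FiveCDesign

DEFAULT_BIN_WIDTH = 80_000
DEFAULT_STEP_DIVISOR = 6


@dataclass
class AnchorProfile:
    """Interaction value per forward fragment, averaged over anchor baits."""

    locus: LocusSpec
    anchor_ids: tuple[str, ...]
    points: tuple[tuple[float, float], ...]  # (forward fragment midpoint, value)
    single_anchor_points: tuple[float, ...] = ()  # midpoints seen by only some anchors

    def __post_init__(self) -> None:
        if any(v < 0 for _, v in self.points):
            raise ValueError("profile values must be >= 0")


@dataclass(frozen=True)
class Bin:
    window: GenomicInterval
    value: float | None  # None = missing (no points in window)
    n_points: int
    points: tuple[tuple[float, float], ...] = ()  # member (midpoint, value) pairs


@dataclass
class BinnedProfile:
    bin_width: int
    step: int
    bins: tuple[Bin, ...]

    @property
    def values(self) -> list[float | None]:
        return [b.value for b in self.bins]


def anchor_average(
    norm: NormalizedIFL,
    design: FiveCDesign,
    fragments: Sequence[RestrictionFragment],
    locus: LocusSpec,
    anchor_ids: Sequence[str] | None = None,
) -> AnchorProfile:
    """Average the per-anchor interaction rows of one normalized library.

    A forward fragment detected from only a subset of the anchors is averaged
    over the anchors that saw it and flagged in ``single_anchor_points``.
    """
    anchor_ids = tuple(anchor_ids or (p.id for p in design.reverse_primers))
    if not anchor_ids:
        raise ValueError("at least one anchor is required")
    mid_by_index = {f.index: f.midpoint for f in fragments}
    per_fwd: dict[str, dict[str, float]] = {}
    for (f, r), v in norm.values.items():
        if r in anchor_ids:
            per_fwd.setdefault(f, {})[r] = v
    if not per_fwd:
        raise ValueError("no contacts involve the requested anchors")
    seen_anchors = {r for d in per_fwd.values() for r in d}
    if len(seen_anchors) < len(anchor_ids):
        missing = set(anchor_ids) - seen_anchors
        raise ValueError(f"anchors with no contacts at all: {sorted(missing)}")
    if len(anchor_ids) > 1 and not any(len(d) > 1 for d in per_fwd.values()):
        raise ValueError("anchors probe entirely disjoint forward-fragment sets")

    fwd_frag = {p.id: p.fragment_index for p in design.forward_primers}
    points = []
    partial = []
    for fid, by_anchor in per_fwd.items():
        mid = mid_by_index[fwd_frag[fid]]
        vals = [by_anchor[a] for a in anchor_ids if a in by_anchor]
        points.append((mid, float(np.mean(vals))))
        if len(vals) < len(anchor_ids):
            partial.append(mid)
    points.sort()
    return AnchorProfile(locus, anchor_ids, tuple(points), tuple(sorted(partial)))


def bin_profile(
    profile: AnchorProfile,
    bin_width: int = DEFAULT_BIN_WIDTH,
    step_divisor: int = DEFAULT_STEP_DIVISOR,
    span: tuple[int, int] | None = None,
) -> BinnedProfile:
    """Sliding-window means of the profile points.

    Windows of ``bin_width`` advance by ``bin_width / step_divisor`` across the
    locus (or an explicit ``span``); a point belongs to a window when its
    midpoint lies in [window start, window start + bin_width) — inclusive
    start, exclusive end.  Windows with no points are missing.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if step_divisor < 1:
        raise ValueError("step_divisor must be >= 1")
    if not profile.points:
        raise ValueError("cannot bin an empty profile")
    step = max(1, bin_width // step_divisor)
    lo, hi = span if span else (profile.locus.interval.start, profile.locus.interval.end)
    mids = np.array([m for m, _ in profile.points])
    vals = np.array([v for _, v in profile.points])
    chrom = profile.locus.interval.chrom
    bins = []
    start = lo
    while start <= hi:
        in_win = (mids >= start) & (mids < start + bin_width)
        n = int(in_win.sum())
        value = float(vals[in_win].mean()) if n else None
        members = tuple(zip(mids[in_win].tolist(), vals[in_win].tolist()))
        bins.append(Bin(GenomicInterval(chrom, start, start + bin_width - 1), value, n, members))
        start += step
    return BinnedProfile(bin_width=bin_width, step=step, bins=tuple(bins))


@dataclass(frozen=True)
class CalledRegion:
    interval: GenomicInterval
    score: float  # peak bin z-score
    tss_distance: float  # signed bp from the TSS to the peak bin centre
    peak_bin: int


def _fit_decay_points(
    dists: np.ndarray, logv: np.ndarray, sigma: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Weighted fit of the monotone decay log v = a - alpha*log(d + c).

    The fitted short-range offset ``c`` captures the flattening of contact
    frequency at distances comparable to the crosslinking reach; without it
    the curvature of the decay near the anchor masquerades as signal.
    Returns fitted parameters applied to *all* distances (``keep`` selects
    the points entering the fit).
    """
    from scipy.optimize import least_squares

    if np.allclose(dists[keep], dists[keep][0]):
        raise ValueError("degenerate decay fit: all points at equal distance to anchor")

    def model_at(p: np.ndarray, d: np.ndarray) -> np.ndarray:
        a, alpha, log_c = p
        return a - alpha * np.log(d + np.exp(log_c))

    def resid(p: np.ndarray) -> np.ndarray:
        return (logv[keep] - model_at(p, dists[keep])) / sigma[keep]

    slope, intercept = np.polyfit(np.log(dists[keep]), logv[keep], 1)
    p0 = np.array([intercept, max(0.1, -slope), np.log(dists.min())])
    fit = least_squares(
        resid, p0, bounds=([-np.inf, 0.0, 0.0], [np.inf, 10.0, np.log(dists.max())])
    )
    return model_at(fit.x, dists)


def _robust_scale(t: np.ndarray) -> tuple[float, float]:
    """Iterated median/MAD location-scale estimate, tolerant of heavy tails."""
    centre = float(np.median(t))
    scale = 1.4826 * float(np.median(np.abs(t - centre)))
    for _ in range(3):
        if scale <= 0:
            return centre, 0.0
        inliers = np.abs(t - centre) <= 3.0 * scale
        if inliers.sum() < 3:
            break
        new_centre = float(np.median(t[inliers]))
        new_scale = 1.4826 * float(np.median(np.abs(t[inliers] - new_centre)))
        if abs(new_scale - scale) < 1e-12:
            centre, scale = new_centre, new_scale
            break
        centre, scale = new_centre, new_scale
    return centre, scale


def call_strong_regions(
    binned: BinnedProfile,
    locus: LocusSpec,
    anchor_midpoints: Sequence[float],
    z_threshold: float = 3.0,
    min_distance: float | None = None,
    local_neighbors: int = 6,
    count_scale: float | None = None,
) -> list[CalledRegion]:
    """Regions whose binned signal exceeds the fitted distance decay.

    A monotone decay (log value linear in log of offset distance to the mean
    anchor midpoint) is fitted over the profile's fragment-level points, with
    outlying points (loops, boundary dips) masked and refitted once; each
    bin's expected value is the mean of the fitted curve at its member
    points, so sparse bins on a steep decay are not penalized for their
    geometry.  Residuals are taken in log space, weighted by an approximate
    per-bin count scale, studentized robustly, and maximal runs of
    consecutive scorable bins with score >= z_threshold are merged into
    regions ranked by peak score.  Bins overlapping an anchor midpoint are
    excluded; bins with no points or zero signal are not scorable.

    ``count_scale`` is the approximate number of sequencing reads behind one
    unit of profile value at one fragment (for a depth-normalized profile:
    number of anchors x total run reads).  When given, residuals are scored
    in Poisson standard-deviation units and the robust scale is floored at 1,
    so a profile that fits the background model perfectly cannot shrink the
    scale and turn count noise into calls; when omitted, only relative read
    masses enter and the scale is purely empirical.
    """
    anchor = float(np.mean(anchor_midpoints))
    min_distance = min_distance if min_distance is not None else binned.step
    scorable = []
    for k, b in enumerate(binned.bins):
        if b.value is None or b.value <= 0:
            continue
        if any(b.window.start <= m <= b.window.end for m in anchor_midpoints):
            continue
        scorable.append((k, b))
    if len(scorable) < 10:
        raise ValueError(f"need >= 10 scorable bins, have {len(scorable)}")
    ks = np.array([k for k, _ in scorable])

    # fragment-level fit: unique profile points inside the scorable bins
    point_map: dict[float, float] = {}
    for _, b in scorable:
        for m, v in b.points:
            point_map[m] = v
    p_mids = np.array(sorted(point_map))
    p_vals = np.array([point_map[m] for m in p_mids])
    positive = p_vals > 0
    p_mids, p_vals = p_mids[positive], p_vals[positive]
    p_dists = np.maximum(np.abs(p_mids - anchor), min_distance)
    p_logv = np.log(p_vals)
    # read mass per point; relative if the depth is unknown
    p_reads = p_vals * count_scale if count_scale else p_vals / p_vals.min()
    p_sigma = 1.0 / np.sqrt(p_reads)

    # mask only upward outliers: loops are point enrichments to exclude from
    # the background, while dips (insulated neighbourhoods) are background
    keep = np.ones(len(p_mids), bool)
    fitted_logv = _fit_decay_points(p_dists, p_logv, p_sigma, keep)
    for _ in range(2):
        t_p = (p_logv - fitted_logv) / p_sigma
        centre, scale = _robust_scale(t_p)
        if scale <= 0:
            break
        new_keep = (t_p - centre) <= 3.0 * scale
        if new_keep.sum() < 5 or (new_keep == keep).all():
            break
        keep = new_keep
        fitted_logv = _fit_decay_points(p_dists, p_logv, p_sigma, keep)

    # local background: broad structure the global decay cannot carry (TAD
    # insulation steps, compartment-scale offsets) shifts whole neighbourhoods
    # of residuals together; the median residual of each point's nearest kept
    # neighbours absorbs it, while a single looping fragment cannot move the
    # median of its neighbourhood.
    resid_p = p_logv - fitted_logv
    baseline = np.zeros(len(p_mids))
    kept_idx = np.where(keep)[0]
    for i in range(len(p_mids)):
        others = kept_idx[kept_idx != i]
        if len(others) == 0:
            continue
        nearest = others[np.argsort(np.abs(p_mids[others] - p_mids[i]))[:local_neighbors]]
        baseline[i] = np.median(resid_p[nearest])
    fitted_logv = fitted_logv + baseline
    fitted_val = dict(zip(p_mids.tolist(), np.exp(fitted_logv).tolist()))

    # bin-level residuals against the mean of the fitted curve at member points
    values, expected, reads = [], [], []
    kept_rows = []
    for row, (k, b) in enumerate(scorable):
        member_fits = [fitted_val[m] for m, v in b.points if m in fitted_val]
        if not member_fits:
            continue
        kept_rows.append(row)
        values.append(b.value)
        expected.append(float(np.mean(member_fits)))
        point_scale = count_scale if count_scale else 1.0 / p_vals.min()
        reads.append(sum(point_map[m] * point_scale for m, v in b.points if m in fitted_val))
    ks = ks[kept_rows]
    values = np.array(values)
    expected = np.array(expected)
    reads = np.array(reads)
    t = (np.log(values) - np.log(expected)) * np.sqrt(reads)
    centre, scale = _robust_scale(t)
    if count_scale:
        scale = max(scale, 1.0)  # t is in Poisson sigma units; never sharper than that
    if scale <= 0:
        return []  # perfectly flat residuals: nothing stands out
    z = (t - centre) / scale

    regions: list[CalledRegion] = []
    run: list[int] = []  # positions into ks / z
    def flush(run: list[int]) -> None:
        if not run:
            return
        peak_pos = max(run, key=lambda p: z[p])
        k_first, k_last = ks[run[0]], ks[run[-1]]
        iv = GenomicInterval(
            locus.interval.chrom,
            binned.bins[k_first].window.start,
            binned.bins[k_last].window.end,
        )
        peak_bin = int(ks[peak_pos])
        centre_iv = binned.bins[peak_bin].window
        regions.append(
            CalledRegion(
                interval=iv,
                score=float(z[peak_pos]),
                tss_distance=signed_tss_distance(centre_iv, locus),
                peak_bin=peak_bin,
            )
        )

    for pos in range(len(ks)):
        if z[pos] >= z_threshold:
            if run and ks[pos] != ks[run[-1]] + 1:
                flush(run)
                run = []
            run.append(pos)
        else:
            flush(run)
            run = []
    flush(run)
    regions.sort(key=lambda r: -r.score)
    return regions


def export_heatmap(
    binned_by_library: dict[str, BinnedProfile],
    path: str | Path | None = None,
    image_path: str | Path | None = None,
    per_row_scaling: bool = False,
) -> pd.DataFrame:
    """Libraries x bins matrix of binned values (missing bins as NA).

    Optionally writes a TSV and/or a heatmap image; returns the matrix.
    """
    profiles = list(binned_by_library.items())
    if not profiles:
        raise ValueError("no profiles to export")
    ref_bins = [(b.window.start, b.window.end) for b in profiles[0][1].bins]
    for name, bp in profiles[1:]:
        if [(b.window.start, b.window.end) for b in bp.bins] != ref_bins:
            raise ValueError(f"bins of library {name!r} are not aligned with the first library")
    columns = [f"{s}-{e}" for s, e in ref_bins]
    data = {
        name: [b.value if b.value is not None else np.nan for b in bp.bins]
        for name, bp in profiles
    }
    mat = pd.DataFrame(data, index=columns).T
    if path is not None:
        mat.to_csv(path, sep="\t", na_rep="NA")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot = mat.to_numpy(float)
        if per_row_scaling:
            denom = np.nanmax(plot, axis=1, keepdims=True)
            denom[denom == 0] = 1.0
            plot = plot / denom
        fig, ax = plt.subplots(figsize=(10, 0.6 * len(mat) + 1.5))
        im = ax.imshow(plot, aspect="auto", cmap="Reds", interpolation="nearest")
        ax.set_yticks(range(len(mat)), mat.index)
        ax.set_xlabel("bin")
        fig.colorbar(im, ax=ax, label="interaction frequency")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return mat


def import_heatmap(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def regions_to_bed(path: str | Path, regions: Sequence[CalledRegion]) -> None:
    """Called regions as 5-column BED (score in column 5, capped at 1000)."""
    with open(path, "w") as fh:
        for k, r in enumerate(regions):
            bed_score = int(min(1000, round(100 * r.score)))
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}"
                f"\tregion_{k + 1}\t{bed_score}\n"
            )
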