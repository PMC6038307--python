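"""Overlap called contact regions with regulatory tracks (DHS, H3K27Ac, CTCF).

A contact region is a candidate regulatory element when it coincides with an
open-chromatin (DNase I hypersensitive) site or an active-enhancer histone
mark, and a candidate loop anchor when a CTCF site lies nearby.  This module
computes, per region and track, the total overlap in bp and the distance to
the nearest feature, and renders a TSS-relative report.

Tracks are plain BED (3 or 5 columns, 0-based half-open on disk, converted to
the package's 1-based inclusive intervals at read time).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome_model import (
    GenomicInterval,
    LocusSpec,
    interval_from_bed_fields,
    interval_gap,
    signed_tss_distance,
)

NO_FEATURE = math.inf  # nearest-feature sentinel for an empty track
DEFAULT_NEAR_BP = 10_000  # "proximity" threshold for the CTCF flag


@dataclass(frozen=True)
class AnnotationTrack:
    name: str
    intervals: tuple[GenomicInterval, ...]
    scores: tuple[float | None, ...] = ()

    def sorted(self) -> "AnnotationTrack":
        order = sorted(range(len(self.intervals)), key=lambda k: (self.intervals[k].start, self.intervals[k].end))
        scores = self.scores if self.scores else tuple([None] * len(self.intervals))
        return AnnotationTrack(
            self.name,
            tuple(self.intervals[k] for k in order),
            tuple(scores[k] for k in order),
        )


@dataclass(frozen=True)
class TrackHit:
    overlap_bp: int
    nearest_distance: float  # 0 if overlapping; inf if the track is empty


@dataclass(frozen=True)
class AnnotatedRegion:
    interval: GenomicInterval
    tss_distance: float  # signed bp
    score: float
    per_track: dict[str, TrackHit]
    flags: dict[str, bool]


def read_bed_track(path: str | Path, name: str | None = None) -> AnnotationTrack:
    intervals = []
    scores: list[float | None] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            intervals.append(interval_from_bed_fields(fields[0], int(fields[1]), int(fields[2])))
            scores.append(float(fields[4]) if len(fields) >= 5 else None)
    return AnnotationTrack(name or Path(path).stem, tuple(intervals), tuple(scores))


def _track_hit(region: GenomicInterval, track: AnnotationTrack) -> TrackHit:
    if not track.intervals:
        return TrackHit(0, NO_FEATURE)
    overlap = sum(region.overlap_bp(iv) for iv in track.intervals)
    nearest = 0.0 if overlap > 0 else float(min(interval_gap(region, iv) for iv in track.intervals))
    return TrackHit(overlap, nearest)


def annotate_regions(
    regions: Sequence,  # CalledRegion-like: .interval and .score
    tracks: Sequence[AnnotationTrack],
    locus: LocusSpec,
    near_bp: int = DEFAULT_NEAR_BP,
) -> list[AnnotatedRegion]:
    """Per region and track: overlap bp, nearest-feature distance, and flags.

    ``coincides_with_<track>`` means overlap > 0; ``near_<track>`` means the
    nearest feature is within ``near_bp``.  Unsorted tracks are sorted with a
    warning; a track on another contig is an error.
    """
    chrom = locus.interval.chrom
    clean_tracks = []
    for track in tracks:
        for iv in track.intervals:
            if iv.chrom != chrom:
                raise ValueError(f"track {track.name!r} has feature on {iv.chrom}, locus is on {chrom}")
        starts = [iv.start for iv in track.intervals]
        if starts != sorted(starts):
            warnings.warn(f"track {track.name!r} is unsorted; sorting internally", stacklevel=2)
            track = track.sorted()
        clean_tracks.append(track)

    annotated = []
    for region in regions:
        iv = region.interval
        per_track = {t.name: _track_hit(iv, t) for t in clean_tracks}
        flags = {}
        for t in clean_tracks:
            hit = per_track[t.name]
            flags[f"coincides_with_{t.name}"] = hit.overlap_bp > 0
            flags[f"near_{t.name}"] = hit.nearest_distance <= near_bp
        annotated.append(
            AnnotatedRegion(
                interval=iv,
                tss_distance=signed_tss_distance(iv, locus),
                score=float(getattr(region, "score", 0.0)),
                per_track=per_track,
                flags=flags,
            )
        )
    return annotated


def region_report(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    """TSS-relative report, ranked by profile score; distances in kb (0.1 kb precision)."""
    rows = []
    for a in sorted(annotated, key=lambda a: -a.score):
        row = {
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "end": a.interval.end,
            "tss_distance_kb": round(a.tss_distance / 1000.0, 1),
            "score": round(a.score, 3),
        }
        for name, hit in a.per_track.items():
            row[f"{name}_overlap_bp"] = hit.overlap_bp
            row[f"{name}_nearest_bp"] = hit.nearest_distance
        for flag, val in a.flags.items():
            row[flag] = bool(val)
        rows.append(row)
    return pd.DataFrame(rows)


def write_region_report(path: str | Path, annotated: Sequence[AnnotatedRegion]) -> None:
    region_report(annotated).to_csv(path, sep="\t", index=False)
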