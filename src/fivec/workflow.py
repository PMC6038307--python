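"""Composed pipeline steps: simulation -> counting -> normalization -> calling.

Thin orchestration over the stage modules, shared by the command-line
interface and by scripted analyses; nothing here adds behaviour of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .junction_quant import IFL, count_junctions
from .normalization import NormalizedIFL, control_ratio, depth_normalize, normalize_library
from .profile_binning import BinnedProfile, CalledRegion, anchor_average, bin_profile, call_strong_regions
from .synthetic_locus import LibrarySpec, RegionSim, SyntheticStudy, simulate_library, simulate_run


def counts_to_ifl(
    counts: dict[tuple[str, str], int], library_id: str, total_run_reads: int
) -> IFL:
    """Wrap a latent truth-count table as an IFL (remaining reads unassigned)."""
    assigned = sum(counts.values())
    return IFL(library_id, dict(counts), total_run_reads, total_run_reads - assigned)


def simulate_study_run(
    study: SyntheticStudy, lib: LibrarySpec, study_share: float = 0.3
) -> tuple[IFL, IFL]:
    """One full sequencing run (study + controls); returns (study IFL, control IFL)."""
    study_region = RegionSim(
        "study", study.design, study.fragments, study.model, weight_share=study_share
    )
    counts = simulate_run([study_region, *study.controls], lib)
    merged_controls: dict[tuple[str, str], int] = {}
    for region in study.controls:
        merged_controls.update(counts[region.name])
    return (
        counts_to_ifl(counts["study"], lib.library_id, lib.total_reads),
        counts_to_ifl(merged_controls, lib.library_id, lib.total_reads),
    )


def count_simulated_library(
    study: SyntheticStudy, lib: LibrarySpec, max_mismatch: int = 2
) -> tuple[IFL, dict[tuple[str, str], int]]:
    """Simulate a study library's reads and count them back; returns (IFL, truth)."""
    records, truth = simulate_library(study.design, study.fragments, study.model, lib)
    ifl = count_junctions(
        (seq for _, seq, _ in records), study.design, max_mismatch=max_mismatch,
        library_id=lib.library_id,
    )
    return ifl, truth


@dataclass
class CallResult:
    binned: BinnedProfile
    regions: list[CalledRegion]
    anchor_midpoints: list[float]


def profile_and_call(
    study: SyntheticStudy,
    norm: NormalizedIFL,
    total_reads: int,
    bin_width: int | None = None,
    step_divisor: int = 6,
    z_threshold: float = 3.0,
) -> CallResult:
    """Anchor-average, bin and call strong regions for one normalized library.

    The default calling window is three times the median fragment size —
    fine enough that one looping fragment dominates its window — advancing by
    a sixth of the window.
    """
    if bin_width is None:
        sizes = sorted(f.length for f in study.fragments)
        bin_width = 3 * sizes[len(sizes) // 2]
    prof = anchor_average(norm, study.design, study.fragments, study.locus)
    binned = bin_profile(prof, bin_width=bin_width, step_divisor=step_divisor)
    mid_by_index = {f.index: f.midpoint for f in study.fragments}
    anchor_mids = [mid_by_index[i] for i in study.anchors]
    regions = call_strong_regions(
        binned,
        study.locus,
        anchor_mids,
        z_threshold=z_threshold,
        count_scale=len(anchor_mids) * total_reads,
    )
    return CallResult(binned, regions, anchor_mids)
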