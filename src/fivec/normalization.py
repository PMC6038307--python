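"""Two-stage inter-library 5C normalization.

Stage 1 (depth): every contact's read count is divided by the total number of
reads of its sequencing run, turning counts into read fractions.

Stage 2 (compaction): over the control regions, the per-contact ratio of a
sample's depth-normalized values to those of a designated reference library is
summarized into a single factor (median over contacts nonzero in both
libraries).  Dividing the sample's study-region data by that factor maps it
onto the reference library's scale; a library twice as "compact" in its
control regions as the reference gets a factor of 2 and is halved.

The reference library normalizes to itself with factor exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .junction_quant import IFL

MIN_SHARED_CONTROL_CONTACTS = 3


@dataclass
class NormalizedIFL:
    """Per-contact normalized interaction frequencies for one library."""

    library_id: str
    values: dict[tuple[str, str], float]
    normalization_factor: float = 1.0
    reference_id: str | None = None
    direction: str = "divide"  # how the factor was applied, recorded for provenance
    depth_normalized: bool = True

    def __post_init__(self) -> None:
        if self.reference_id == self.library_id and self.normalization_factor != 1.0:
            raise ValueError("reference library must carry normalization_factor 1")


def depth_normalize(ifl: IFL) -> NormalizedIFL:
    """Divide each contact's count by the run's total read count."""
    if ifl.total_run_reads <= 0:
        raise ValueError(f"library {ifl.library_id!r} has zero total reads")
    values = {pair: c / ifl.total_run_reads for pair, c in ifl.counts.items()}
    return NormalizedIFL(ifl.library_id, values)


def control_ratio(
    sample_controls: NormalizedIFL,
    reference_controls: NormalizedIFL,
    summary: str = "median",
) -> float:
    """Compaction factor: summary of per-contact sample/reference ratios.

    Only contacts nonzero in both libraries enter; at least
    ``MIN_SHARED_CONTROL_CONTACTS`` are required.  A library compared against
    itself yields exactly 1.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    if sample_controls.library_id == reference_controls.library_id:
        if sample_controls.values == reference_controls.values:
            return 1.0
    shared = [
        sample_controls.values[k] / reference_controls.values[k]
        for k in sample_controls.values.keys() & reference_controls.values.keys()
        if sample_controls.values[k] > 0 and reference_controls.values[k] > 0
    ]
    if len(shared) < MIN_SHARED_CONTROL_CONTACTS:
        raise ValueError(
            f"insufficient control coverage: {len(shared)} shared nonzero contacts "
            f"(need >= {MIN_SHARED_CONTROL_CONTACTS})"
        )
    ratios = np.asarray(shared)
    return float(np.median(ratios) if summary == "median" else ratios.mean())


def apply_factor(
    study: IFL,
    factor: float,
    reference_id: str | None = None,
    direction: str = "divide",
    depth_normalize_study: bool = True,
) -> NormalizedIFL:
    """Rescale a library's study-region data by its compaction factor.

    Default pathway: value = (raw_count / total_run_reads) / factor, i.e.
    depth normalization followed by division by the sample-over-reference
    control ratio, which places every library on the reference scale.  Set
    ``depth_normalize_study=False`` to scale raw counts directly, or
    ``direction='multiply'`` for the opposite convention; the choice is
    recorded on the result.
    """
    if factor <= 0:
        raise ValueError(f"normalization factor must be positive, got {factor}")
    if direction not in ("divide", "multiply"):
        raise ValueError("direction must be 'divide' or 'multiply'")
    scale = (1.0 / factor) if direction == "divide" else factor
    denom = study.total_run_reads if depth_normalize_study else 1
    if depth_normalize_study and denom <= 0:
        raise ValueError("cannot depth-normalize a library with zero reads")
    values = {pair: c / denom * scale for pair, c in study.counts.items()}
    return NormalizedIFL(
        library_id=study.library_id,
        values=values,
        normalization_factor=factor,
        reference_id=reference_id,
        direction=direction,
        depth_normalized=depth_normalize_study,
    )


def normalize_library(
    study: IFL,
    sample_controls: IFL,
    reference_controls: IFL,
    reference_id: str,
    summary: str = "median",
    depth_normalize_study: bool = True,
) -> NormalizedIFL:
    """Full two-stage pipeline for one library against a reference."""
    factor = control_ratio(
        depth_normalize(sample_controls), depth_normalize(reference_controls), summary=summary
    )
    if study.library_id == reference_id:
        factor = 1.0
    return apply_factor(
        study, factor, reference_id=reference_id, depth_normalize_study=depth_normalize_study
    )


def per_region_factors(
    sample_controls_by_region: dict[str, NormalizedIFL],
    reference_controls_by_region: dict[str, NormalizedIFL],
    summary: str = "median",
) -> dict[str, float]:
    """Per-control-region breakdown of the compaction factor (diagnostic)."""
    return {
        region: control_ratio(sample_controls_by_region[region], reference_controls_by_region[region], summary)
        for region in sample_controls_by_region
    }


def write_normalized_ifl(path: str | Path, norm: NormalizedIFL) -> None:
    with open(path, "w") as fh:
        fh.write(f"# library_id\t{norm.library_id}\n")
        fh.write(f"# reference_id\t{norm.reference_id or ''}\n")
        fh.write(f"# factor\t{norm.normalization_factor!r}\n")
        fh.write(f"# direction\t{norm.direction}\n")
        fh.write(f"# depth_normalized\t{norm.depth_normalized}\n")
        fh.write("fwd_id\trev_id\tvalue\n")
        for (f, r), v in sorted(norm.values.items()):
            fh.write(f"{f}\t{r}\t{v!r}\n")


def read_normalized_ifl(path: str | Path) -> NormalizedIFL:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, val = line[2:].rstrip("\n").partition("\t")
                meta[key] = val
            elif line.startswith("fwd_id"):
                continue
            elif line.strip():
                f, r, v = line.rstrip("\n").split("\t")
                rows.append(((f, r), float(v)))
    return NormalizedIFL(
        library_id=meta.get("library_id", "library"),
        values=dict(rows),
        normalization_factor=float(meta.get("factor", "1") or 1),
        reference_id=meta.get("reference_id") or None,
        direction=meta.get("direction", "divide"),
        depth_normalized=meta.get("depth_normalized", "True") == "True",
    )
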