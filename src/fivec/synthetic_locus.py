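"""Synthetic 5C study: a toy locus with planted TADs, a boundary and loops.

Real 5C experiments on a disease locus come with nuisance structure the
analysis must cope with: power-law distance decay of contacts, insulation at
topological domain (TAD) boundaries, specific promoter-enhancer loops, and
per-library differences in sequencing depth and chromatin compaction.  This
module plants all of those with known parameters so every downstream stage —
junction counting, control-region normalization, binning, strong-contact
calling — can be checked against ground truth.

The contact model gives fragment pair (i, j) the relative weight

    w_ij = (|mid_i - mid_j| + d0)^(-alpha) * beta^(boundaries crossed) * lambda_ij

with ``alpha`` the decay exponent, ``d0`` a short-range saturation offset,
``beta`` in (0, 1] the per-boundary insulation factor and ``lambda_ij >= 1``
a loop enrichment.  The defaults (alpha = 1, d0 = 5 kb, beta = 0.3) are
fabricated to mimic the qualitative decay and boundary dip of published 5C
profiles; they are not estimates from any dataset.

A sequencing run is modelled as one multinomial over all countable contacts
plus a large absorbing *background* category — the non-junction, unassignable
material that dominates real amplicon runs.  The compaction factor ``gamma``
of a library scales the read fraction of every probed region (study and
control alike) against that fixed background, which is what makes it
identifiable: a multinomial over probed contacts alone would renormalize
gamma away.  Depth normalization then leaves each contact's expected fraction
proportional to gamma, the control-ratio step estimates gamma from the
control regions, and dividing the study data by it restores the reference
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gzip

import numpy as np

from .genome_model import (
    GenomicInterval,
    LocusSpec,
    RestrictionFragment,
    digest,
)
from .primer_design import A_KEY_TAIL, P1_KEY_TAIL, DesignConfig, FiveCDesign, design_primers

_BASES = np.array(list("ACGT"))
ECORI_SITE = "GAATTC"


@dataclass(frozen=True)
class ContactModelSpec:
    decay_exponent: float = 1.0
    decay_offset: float = 5_000.0
    tad_partitions: tuple[GenomicInterval, ...] = ()
    boundary_insulation: float = 1.0
    loops: tuple[tuple[int, int, float], ...] = ()  # (fragment_i, fragment_j, enrichment)

    def __post_init__(self) -> None:
        if not (0.0 < self.boundary_insulation <= 1.0):
            raise ValueError("boundary_insulation must be in (0, 1]")
        for i, j, lam in self.loops:
            if lam < 1.0:
                raise ValueError(f"loop enrichment must be >= 1, got {lam} for ({i}, {j})")
        for a, b in zip(self.tad_partitions, self.tad_partitions[1:]):
            if b.start <= a.end:
                raise ValueError("tad_partitions must be non-overlapping and sorted")

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Boundary positions: the joints between consecutive TAD partitions."""
        return tuple((a.end + b.start) / 2.0 for a, b in zip(self.tad_partitions, self.tad_partitions[1:]))


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    total_reads: int
    compaction_factor: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if not (0.0 <= self.error_rate < 0.05):
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.compaction_factor <= 0:
            raise ValueError("compaction_factor must be positive")


def generate_locus(
    length: int,
    n_fragments: int,
    seed: int,
    chrom: str = "chrSim",
    origin: int = 1,
    jitter: float = 0.25,
    tss_fragment: int | None = None,
) -> tuple[str, list[RestrictionFragment], LocusSpec]:
    """Random locus whose EcoRI digest has exactly ``n_fragments`` fragments.

    Cut sites are planted at jittered even spacing and every spurious GAATTC
    is destroyed by a single-base substitution.  The TSS is placed just inside
    the 5' end of ``tss_fragment`` (default: the middle fragment), standing in
    for a promoter at the centre of the probed domain.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if length / n_fragments < 500:
        raise ValueError(f"infeasible spacing: {length} bp / {n_fragments} fragments < 500 bp")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)

    spacing = length / n_fragments
    cut_starts = []  # 0-based offsets where a new fragment starts
    for k in range(1, n_fragments):
        lo = int((k - jitter / 2) * spacing)
        hi = int((k + jitter / 2) * spacing)
        cut_starts.append(int(rng.integers(lo, max(lo + 1, hi))))
    planted = []  # 0-based site match positions
    for c in cut_starts:
        p = c - 1  # digest cuts at match + 1 (G^AATTC)
        seq[p : p + 6] = list(ECORI_SITE)
        planted.append(p)
    planted_set = set(planted)
    protected = {q for p in planted_set for q in range(p, p + 6)}

    # destroy spurious sites; substitutions may create new ones, so iterate
    s = "".join(seq)
    for _ in range(50):
        spurious = [
            p
            for p in _find_all(s, ECORI_SITE)
            if p not in planted_set
        ]
        if not spurious:
            break
        seq = np.array(list(s))
        for p in spurious:
            positions = [q for q in range(p, p + 6) if q not in protected]
            if not positions:  # fully inside a planted site: impossible (no self-overlap)
                continue
            q = int(rng.choice(positions))
            current = seq[q]
            seq[q] = rng.choice([b for b in "ACGT" if b != current])
        s = "".join(seq)
    else:
        raise RuntimeError("could not clear spurious restriction sites")

    fragments = digest(s, origin=origin, chrom=chrom)
    assert len(fragments) == n_fragments, (len(fragments), n_fragments)

    tf = n_fragments // 2 if tss_fragment is None else tss_fragment
    promoter = fragments[tf]
    tss = promoter.interval.start + min(200, promoter.length // 4)
    locus = LocusSpec(
        name="synthetic_locus",
        interval=GenomicInterval(chrom, origin, origin + length - 1),
        tss=tss,
        gene_strand="+",
    )
    return s, fragments, locus


def _find_all(s: str, pat: str) -> list[int]:
    out = []
    p = s.find(pat)
    while p != -1:
        out.append(p)
        p = s.find(pat, p + 1)
    return out


def expected_contact(
    i: RestrictionFragment, j: RestrictionFragment, model: ContactModelSpec
) -> float:
    """Deterministic relative contact weight of a fragment pair (symmetric)."""
    if i.index == j.index:
        raise ValueError("expected_contact is defined for distinct fragments")
    d = abs(i.midpoint - j.midpoint)
    w = (d + model.decay_offset) ** (-model.decay_exponent)
    lo, hi = sorted((i.midpoint, j.midpoint))
    crossed = sum(1 for b in model.boundaries if lo < b < hi)
    w *= model.boundary_insulation**crossed
    for a, b, lam in model.loops:
        if {a, b} == {i.index, j.index}:
            w *= lam
    return w


# ---------------------------------------------------------------------------
# Run simulation


@dataclass(frozen=True)
class RegionSim:
    """One probed region of a sequencing run (study or control).

    ``weight_share`` is the region's expected fraction of the run's reads at
    compaction gamma = 1; the remainder of the run is absorbing background.
    """

    name: str
    design: FiveCDesign
    fragments: tuple[RestrictionFragment, ...]
    model: ContactModelSpec
    weight_share: float = 0.3
    is_control: bool = False


def _pair_weights(region: RegionSim) -> tuple[list[tuple[str, str]], np.ndarray]:
    frag_by_index = {f.index: f for f in region.fragments}
    pairs = region.design.valid_pairs()
    if not pairs:
        raise ValueError(f"region {region.name!r} has zero valid (forward, reverse) pairs")
    fwd_frag = {p.id: frag_by_index[p.fragment_index] for p in region.design.forward_primers}
    rev_frag = {p.id: frag_by_index[p.fragment_index] for p in region.design.reverse_primers}
    w = np.array(
        [expected_contact(fwd_frag[f], rev_frag[r], region.model) for f, r in pairs], float
    )
    return pairs, w


def simulate_run(
    regions: Sequence[RegionSim], lib: LibrarySpec
) -> dict[str, dict[tuple[str, str], int]]:
    """Latent true junction counts for one sequencing run.

    One multinomial of ``lib.total_reads`` over the union of all regions'
    countable contacts plus an absorbing background category: each region's
    contacts get probability ``gamma * weight_share * w_pair / sum(w)``, and
    the background soaks up the rest of the run (it must stay positive — a
    run cannot be more than 100% probed junctions).
    """
    rng = np.random.default_rng(lib.seed)
    all_pairs: list[tuple[str, tuple[str, str]]] = []
    probs: list[float] = []
    for region in regions:
        pairs, w = _pair_weights(region)
        w = w / w.sum() * region.weight_share * lib.compaction_factor
        all_pairs.extend((region.name, p) for p in pairs)
        probs.extend(w.tolist())
    background = 1.0 - sum(probs)
    if background < -1e-9:
        raise ValueError(
            f"probed read fractions sum to {sum(probs):.3f} > 1 at "
            f"compaction {lib.compaction_factor}; lower the regions' weight_share"
        )
    counts = rng.multinomial(lib.total_reads, np.asarray(probs + [max(0.0, background)]))
    out: dict[str, dict[tuple[str, str], int]] = {r.name: {} for r in regions}
    for (name, pair), c in zip(all_pairs, counts[:-1]):
        out[name][pair] = int(c)
    return out


def _mutate_reads(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0 or not reads:
        return reads
    out = []
    for read in reads:
        n_err = rng.binomial(len(read), error_rate)
        if n_err == 0:
            out.append(read)
            continue
        arr = list(read)
        for pos in rng.choice(len(read), size=n_err, replace=False):
            arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
        out.append("".join(arr))
    return out


def reads_from_counts(
    counts: dict[tuple[str, str], int],
    design: FiveCDesign,
    error_rate: float,
    rng: np.random.Generator,
    include_tails: bool = False,
    read_prefix: str = "read",
) -> list[tuple[str, str, str]]:
    """FASTQ records (title, seq, qual) for a latent count table.

    Each read is the junction sequence forward.genomic_seq + reverse.genomic_seq,
    emitted 5'->3' from the forward side (single-end), with i.i.d. substitution
    errors at ``error_rate``; record order follows the sorted contact keys.
    """
    fwd = {p.id: p for p in design.forward_primers}
    rev = {p.id: p for p in design.reverse_primers}
    seqs: list[str] = []
    names: list[str] = []
    for (f, r), c in sorted(counts.items()):
        if c == 0:
            continue
        junction = fwd[f].genomic_seq + rev[r].genomic_seq
        if include_tails:
            junction = A_KEY_TAIL + junction + P1_KEY_TAIL
        seqs.extend([junction] * c)
        names.extend(f"{read_prefix}_{f}_{r}_{k}" for k in range(c))
    seqs = _mutate_reads(seqs, error_rate, rng)
    return [(name, s, "I" * len(s)) for name, s in zip(names, seqs)]


def simulate_library(
    design: FiveCDesign,
    fragments: Sequence[RestrictionFragment],
    model: ContactModelSpec,
    lib: LibrarySpec,
    include_tails: bool = False,
) -> tuple[list[tuple[str, str, str]], dict[tuple[str, str], int]]:
    """Simulate one study-region library: FASTQ records plus latent true counts.

    Single-region view of the run: every read is a study junction (the
    background and the compaction factor only matter to multi-region runs),
    so the latent counts sum exactly to ``lib.total_reads``.
    """
    if not design.forward_primers or not design.reverse_primers:
        raise ValueError("design needs at least one forward and one reverse primer")
    from dataclasses import replace as _replace

    region = RegionSim("study", design, tuple(fragments), model, weight_share=1.0)
    counts = simulate_run([region], _replace(lib, compaction_factor=1.0))["study"]
    rng = np.random.default_rng((lib.seed, 1))
    records = reads_from_counts(
        counts, design, lib.error_rate, rng, include_tails, read_prefix=lib.library_id
    )
    return records, counts


def simulate_controls(
    control_regions: Sequence[RegionSim],
    lib: LibrarySpec,
) -> dict[str, dict[tuple[str, str], int]]:
    """Latent control-region counts of a run (the rest of the run is background).

    Each control contact's expected read fraction is gamma * share * w_pair,
    so the per-contact ratio of a sample's depth-normalized counts to a
    gamma = 1 reference at equal depth is exactly the sample's compaction
    factor — the quantity the control-ratio normalization recovers.
    """
    return simulate_run(list(control_regions), lib)


def write_fastq(path: str | Path, records: Sequence[tuple[str, str, str]]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Default study conditions


@dataclass(frozen=True)
class SyntheticStudy:
    """A fully assembled synthetic 5C study with its ground truth."""

    sequence: str
    fragments: tuple[RestrictionFragment, ...]
    locus: LocusSpec
    design: FiveCDesign
    model: ContactModelSpec
    controls: tuple[RegionSim, ...]
    anchors: tuple[int, ...]
    loop_fragments: tuple[int, ...]


# Default geometry: a ~280 kb locus of 26 EcoRI fragments (~11 kb each), an
# anchored design with 2 promoter baits and 24 forward primers mirroring the
# published 5C layout, one TAD boundary at ~72% of the locus, and 3 planted
# promoter loops (two within the promoter TAD, one across the boundary).
DEFAULT_LOCUS_LENGTH = 280_000
DEFAULT_N_FRAGMENTS = 26
DEFAULT_ANCHORS = (12, 13)
DEFAULT_LOOP_TARGETS = (3, 7, 22)
DEFAULT_LOOP_ENRICHMENT = 8.0
DEFAULT_TOTAL_READS = 100_000


def default_model(
    fragments: Sequence[RestrictionFragment],
    locus: LocusSpec,
    anchors: Sequence[int] = DEFAULT_ANCHORS,
    loop_targets: Sequence[int] = DEFAULT_LOOP_TARGETS,
    loop_enrichment: float = DEFAULT_LOOP_ENRICHMENT,
    boundary_insulation: float = 0.3,
    decay_exponent: float = 1.0,
) -> ContactModelSpec:
    chrom = locus.interval.chrom
    b = locus.interval.start + int(0.72 * locus.interval.length)
    tads = (
        GenomicInterval(chrom, locus.interval.start, b),
        GenomicInterval(chrom, b + 1, locus.interval.end),
    )
    anchors = tuple(anchors)
    loops = tuple(
        (anchors[k % len(anchors)], t, loop_enrichment) for k, t in enumerate(loop_targets)
    )
    return ContactModelSpec(
        decay_exponent=decay_exponent,
        decay_offset=5_000.0,
        tad_partitions=tads,
        boundary_insulation=boundary_insulation,
        loops=loops,
    )


def build_study(
    seed: int,
    with_loops: bool = True,
    boundary_insulation: float = 0.3,
    design_config: DesignConfig | None = None,
) -> SyntheticStudy:
    """Assemble the default synthetic study: locus, design, model and controls."""
    config = design_config or DesignConfig()
    sequence, fragments, locus = generate_locus(
        DEFAULT_LOCUS_LENGTH, DEFAULT_N_FRAGMENTS, seed=seed, tss_fragment=DEFAULT_ANCHORS[0]
    )
    design = design_primers(
        fragments, sequence, config, scheme="anchored", anchors=DEFAULT_ANCHORS, id_prefix="LOC"
    )
    model = default_model(
        fragments,
        locus,
        loop_targets=DEFAULT_LOOP_TARGETS if with_loops else (),
        boundary_insulation=boundary_insulation,
    )
    controls = build_controls(seed)
    return SyntheticStudy(
        sequence=sequence,
        fragments=tuple(fragments),
        locus=locus,
        design=design,
        model=model,
        controls=controls,
        anchors=DEFAULT_ANCHORS,
        loop_fragments=tuple(DEFAULT_LOOP_TARGETS) if with_loops else (),
    )


def build_controls(seed: int, config: DesignConfig | None = None) -> tuple[RegionSim, ...]:
    """Two alternating-design control regions.

    Structured like typical 5C normalization controls: a small gene region
    (5 fragments, 2 forward / 3 reverse) and a larger gene-desert region
    (26 fragments, 13 forward / 13 reverse); both carry a plain distance-decay
    model with no TADs or loops.
    """
    config = config or DesignConfig()
    out = []
    for k, (name, length, n_frag, start, chrom) in enumerate(
        (
            ("ctrl_gene", 50_000, 5, "reverse", "chrCtrlA"),
            ("ctrl_desert", 260_000, 26, "forward", "chrCtrlB"),
        )
    ):
        seq, frags, _locus = generate_locus(
            length, n_frag, seed=(seed * 31 + k + 1) % 2**31, chrom=chrom
        )
        design = design_primers(
            frags, seq, config, scheme="alternating", id_prefix=name, alternating_start=start
        )
        model = ContactModelSpec(decay_exponent=1.0, decay_offset=5_000.0)
        out.append(
            RegionSim(name, design, tuple(frags), model, weight_share=0.06, is_control=True)
        )
    return tuple(out)
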