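"""5C primer design over a restriction-fragment map.

One oligo per eligible fragment.  Forward primers read the top strand of the
fragment end abutting the *downstream* cut site; reverse primers read the top
strand starting at the fragment's *upstream* cut site.  Stored that way, the
sequence of a ligation junction between a forward fragment and a reverse
fragment is simply ``forward.genomic_seq + reverse.genomic_seq``, which is what
the junction counter reconstructs.

Two design schemes are supported, mirroring common 5C practice:

* ``anchored`` — reverse "bait" primers on a handful of anchor fragments (the
  promoter), forward primers tiling every other eligible fragment;
* ``alternating`` — forward/reverse orientation alternates along the eligible
  fragments, used for control regions.

Fragments that cannot carry a good primer are kept in the design with an
``excluded_reason`` (``too_long``, ``too_short``, ``low_complexity``,
``multi_target``), so the fragment map and the primer table stay aligned.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .genome_model import RestrictionFragment, reverse_complement

# Universal amplification/sequencing adapter tails (Ion Torrent A-key / P1-key).
A_KEY_TAIL = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
P1_KEY_TAIL = "ATCACCGACTGCCCATAGAGAGG"

EXCLUSION_REASONS = ("too_long", "too_short", "low_complexity", "multi_target")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design targets and filters.

    optimal_length / optimal_tm are the oligo targets (30 nt, 60 °C);
    fragments longer than ``max_fragment_length`` (20 kb) or shorter than
    ``min_fragment_length`` are not probed.  ``uniqueness_k`` is the k-mer size
    of the multi-target screen: a primer whose every placement must be unique
    is rejected if any of its k-mers recurs elsewhere in the sequence universe.
    ``low_complexity_threshold`` is the minimum dinucleotide entropy of the
    primer, as a fraction of the 4-bit maximum.
    """

    optimal_length: int = 30
    optimal_tm: float = 60.0
    max_fragment_length: int = 20_000
    min_fragment_length: int = 100
    length_slack: int = 5
    uniqueness_k: int = 16
    low_complexity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.optimal_length < 15:
            raise ValueError("optimal_length must be >= 15")
        if self.max_fragment_length <= self.min_fragment_length:
            raise ValueError("max_fragment_length must exceed min_fragment_length")


@dataclass(frozen=True)
class FiveCPrimer:
    id: str
    fragment_index: int
    orientation: str  # "forward" | "reverse"
    genomic_seq: str  # top-strand sequence; junction = fwd.genomic_seq + rev.genomic_seq
    tm: float
    oligo: str
    phosphorylated_5p: bool = False  # chemistry flag for reverse primers, not used in analysis
    excluded_reason: str | None = None


@dataclass(frozen=True)
class FiveCDesign:
    scheme: str  # "anchored" | "alternating"
    primers: tuple[FiveCPrimer, ...]
    anchor_fragment_indices: tuple[int, ...] = ()
    exclusions: tuple[tuple[int, str], ...] = ()  # (fragment_index, reason)

    @property
    def forward_primers(self) -> tuple[FiveCPrimer, ...]:
        return tuple(p for p in self.primers if p.orientation == "forward")

    @property
    def reverse_primers(self) -> tuple[FiveCPrimer, ...]:
        return tuple(p for p in self.primers if p.orientation == "reverse")

    def primer_by_id(self, pid: str) -> FiveCPrimer:
        for p in self.primers:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def valid_pairs(self) -> list[tuple[str, str]]:
        """All countable (forward id, reverse id) contacts under this design."""
        return [
            (f.id, r.id)
            for f in self.forward_primers
            for r in self.reverse_primers
            if f.fragment_index != r.fragment_index
        ]


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Uses the nearest-neighbor thermodynamic model with 50 mM Na+ and 25 nM
    oligo on each side (entropy-based monovalent-salt correction).
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes not supported: {seq!r}")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=50, dnac1=25, dnac2=25, saltcorr=5))


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide composition."""
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def add_tails(primer: FiveCPrimer) -> str:
    """Attach the universal tail: A-key 5' of forward, P1-key 3' of reverse."""
    if primer.orientation == "forward":
        return A_KEY_TAIL + primer.genomic_seq
    if primer.orientation == "reverse":
        return primer.genomic_seq + P1_KEY_TAIL
    raise ValueError(f"orientation not set: {primer.orientation!r}")


def _build_kmer_counts(universe: Iterable[str], k: int) -> Counter:
    counts: Counter = Counter()
    for seq in universe:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    return counts


def _is_multi_target(primer_seq: str, kmer_counts: Counter, k: int) -> bool:
    # every k-mer of a unique primer occurs exactly once in the universe
    for i in range(len(primer_seq) - k + 1):
        kmer = primer_seq[i : i + k]
        if kmer_counts.get(kmer, 0) > 1 or kmer_counts.get(reverse_complement(kmer), 0) > 0:
            return True
    return False


def _pick_primer_seq(region: str, anchored_end: str, config: DesignConfig) -> tuple[str, float]:
    """Choose the primer length nearest optimal_tm within ±length_slack of optimal_length.

    ``region`` is top-strand fragment sequence; the primer always ends at the
    restriction site, i.e. it is a suffix (``anchored_end='3p'``, forward) or a
    prefix (``anchored_end='5p'``, reverse) of the fragment.  Ties in |Tm - target|
    break toward the shorter oligo.
    """
    best: tuple[float, int, str, float] | None = None
    for length in range(
        max(15, config.optimal_length - config.length_slack),
        config.optimal_length + config.length_slack + 1,
    ):
        if length > len(region):
            break
        cand = region[-length:] if anchored_end == "3p" else region[:length]
        if "N" in cand:
            continue
        tm = melting_temperature(cand)
        key = (abs(tm - config.optimal_tm), length)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cand, tm)
    if best is None:
        raise ValueError("no candidate primer without N in the target region")
    return best[2], best[3]


def design_primers(
    fragments: Sequence[RestrictionFragment],
    sequence: str,
    config: DesignConfig,
    scheme: str,
    anchors: Sequence[int] = (),
    sequence_origin: int = 1,
    id_prefix: str = "5C",
    alternating_start: str = "forward",
) -> FiveCDesign:
    """Design one 5C primer per eligible fragment under the given scheme.

    ``sequence`` is the digested locus sequence, with ``fragments`` produced by
    :func:`fivec.genome_model.digest` over it; it also serves as the uniqueness
    universe for the multi-target screen.
    """
    if scheme not in ("anchored", "alternating"):
        raise ValueError(f"unknown scheme {scheme!r}")
    anchors = tuple(anchors)
    if scheme == "anchored" and not anchors:
        raise ValueError("anchored scheme requires at least one anchor fragment")
    if scheme == "alternating" and anchors:
        raise ValueError("alternating scheme takes no anchors")
    valid_idx = {f.index for f in fragments}
    for a in anchors:
        if a not in valid_idx:
            raise IndexError(f"anchor fragment index {a} out of range")

    seq = sequence.upper()
    kmer_counts = _build_kmer_counts([seq], config.uniqueness_k)

    exclusions: list[tuple[int, str]] = []
    eligible: list[tuple[RestrictionFragment, str, float, str]] = []  # frag, seq, tm, frag_seq
    for frag in fragments:
        lo = frag.interval.start - sequence_origin
        hi = frag.interval.end - sequence_origin + 1
        frag_seq = seq[lo:hi]
        if frag.length > config.max_fragment_length:
            exclusions.append((frag.index, "too_long"))
            continue
        if frag.length < config.min_fragment_length:
            exclusions.append((frag.index, "too_short"))
            continue
        eligible.append((frag, frag_seq))

    if alternating_start not in ("forward", "reverse"):
        raise ValueError("alternating_start must be 'forward' or 'reverse'")
    start_parity = 0 if alternating_start == "forward" else 1

    def orientation_for(frag: RestrictionFragment, ordinal: int) -> str:
        if scheme == "anchored":
            return "reverse" if frag.index in anchors else "forward"
        return "forward" if (ordinal + start_parity) % 2 == 0 else "reverse"

    primers: list[FiveCPrimer] = []
    for ordinal, (frag, frag_seq) in enumerate(eligible):
        orient = orientation_for(frag, ordinal)
        try:
            genomic_seq, tm = _pick_primer_seq(
                frag_seq, "3p" if orient == "forward" else "5p", config
            )
        except ValueError:
            exclusions.append((frag.index, "low_complexity"))
            continue
        max_entropy = 4.0  # log2(16) possible dinucleotides
        if dinucleotide_entropy(genomic_seq) < config.low_complexity_threshold * max_entropy:
            exclusions.append((frag.index, "low_complexity"))
            continue
        if _is_multi_target(genomic_seq, kmer_counts, config.uniqueness_k):
            exclusions.append((frag.index, "multi_target"))
            continue
        pid = f"{id_prefix}_{'F' if orient == 'forward' else 'R'}_{frag.index:03d}"
        primer = FiveCPrimer(
            id=pid,
            fragment_index=frag.index,
            orientation=orient,
            genomic_seq=genomic_seq,
            tm=tm,
            oligo="",
            phosphorylated_5p=(orient == "reverse"),
        )
        primers.append(replace(primer, oligo=add_tails(primer)))

    for a in anchors:
        if a in {idx for idx, _ in exclusions}:
            reason = dict(exclusions)[a]
            raise ValueError(f"anchor fragment {a} excluded ({reason})")

    return FiveCDesign(
        scheme=scheme,
        primers=tuple(primers),
        anchor_fragment_indices=anchors,
        exclusions=tuple(exclusions),
    )


def design_to_table(
    design: FiveCDesign, fragments: Sequence[RestrictionFragment] | None = None
) -> pd.DataFrame:
    """Primer table (one row per primer plus one per excluded fragment)."""
    by_index = {f.index: f for f in fragments} if fragments else {}
    rows = []
    for p in design.primers:
        frag = by_index.get(p.fragment_index)
        rows.append(
            {
                "id": p.id,
                "fragment_index": p.fragment_index,
                "chrom": frag.interval.chrom if frag else "",
                "start": frag.interval.start if frag else pd.NA,
                "end": frag.interval.end if frag else pd.NA,
                "orientation": p.orientation,
                "genomic_seq": p.genomic_seq,
                "oligo": p.oligo,
                "tm": round(p.tm, 2),
                "excluded_reason": "",
            }
        )
    for idx, reason in design.exclusions:
        frag = by_index.get(idx)
        rows.append(
            {
                "id": "",
                "fragment_index": idx,
                "chrom": frag.interval.chrom if frag else "",
                "start": frag.interval.start if frag else pd.NA,
                "end": frag.interval.end if frag else pd.NA,
                "orientation": "",
                "genomic_seq": "",
                "oligo": "",
                "tm": pd.NA,
                "excluded_reason": reason,
            }
        )
    return pd.DataFrame(rows).sort_values("fragment_index", kind="stable").reset_index(drop=True)


def write_design_table(path: str | Path, design: FiveCDesign, fragments=None) -> None:
    design_to_table(design, fragments).to_csv(path, sep="\t", index=False)
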