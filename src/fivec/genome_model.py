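"""Coordinate conventions, restriction digestion and in-silico PCR.

All public coordinates are 1-based and inclusive on both ends, matching the
UCSC-text style in which locus boundaries are usually quoted (e.g.
``chr4:88,560,000-89,230,000``).  BED files are 0-based half-open; the
conversion happens here, at the file boundary, and nowhere else.

``N`` bases never match a restriction site or a primer.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval on a named contig (1-based, inclusive ends)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection, 0 if disjoint or on different contigs."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two intervals (0 when overlapping or abutting)."""
    if a.chrom != b.chrom:
        raise ValueError(f"contig mismatch: {a.chrom} vs {b.chrom}")
    if a.overlap_bp(b) > 0:
        return 0
    if b.start > a.end:
        return b.start - a.end - 1
    return a.start - b.end - 1


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment of a digested contig; fragments abut exactly and tile the locus."""

    interval: GenomicInterval
    index: int

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class LocusSpec:
    """A named study locus with its transcriptional start site."""

    name: str
    interval: GenomicInterval
    tss: int
    gene_strand: str = "+"

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss <= self.interval.end):
            raise ValueError(
                f"tss {self.tss} outside locus {self.interval.start}-{self.interval.end}"
            )
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")


def find_sites(sequence: str, site: str) -> list[int]:
    """0-based start positions of exact occurrences of ``site`` (overlaps allowed).

    ``N`` in the sequence never matches.
    """
    site = site.upper()
    if not site or set(site) - set("ACGT"):
        raise ValueError(f"restriction site must be non-empty ACGT, got {site!r}")
    seq = sequence.upper()
    hits = []
    pos = seq.find(site)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(site, pos + 1)
    return hits


def digest(
    sequence: str,
    origin: int = 1,
    chrom: str = "locus",
    site: str = "GAATTC",
    cut_offset: int = 1,
) -> list[RestrictionFragment]:
    """In-silico restriction digest of ``sequence``.

    The enzyme cuts the top strand at ``site match + cut_offset`` (EcoRI default
    G^AATTC); the 4-nt 5' overhang is not modelled because 5C works at fragment
    resolution.  Fragments are returned in genomic order, abutting exactly, and
    tile ``[origin, origin + len(sequence) - 1]``.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = set(sequence.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    if not (0 <= cut_offset <= len(site)):
        raise ValueError(f"cut_offset {cut_offset} outside [0, {len(site)}]")

    n = len(sequence)
    # cut points as 0-based offsets where a new fragment starts
    cuts = sorted({p + cut_offset for p in find_sites(sequence, site) if 0 < p + cut_offset < n})
    bounds = [0] + cuts + [n]
    frags = []
    for k in range(len(bounds) - 1):
        start = origin + bounds[k]
        end = origin + bounds[k + 1] - 1
        frags.append(RestrictionFragment(GenomicInterval(chrom, start, end), index=k))
    return frags


def signed_tss_distance(x: GenomicInterval, locus: LocusSpec) -> float:
    """Signed distance from the locus TSS to the midpoint of ``x``, in bp.

    Negative values are upstream of the gene (5'), regardless of which genomic
    strand the gene is on.
    """
    if x.chrom != locus.interval.chrom:
        raise ValueError(f"contig mismatch: {x.chrom} vs {locus.interval.chrom}")
    sign = 1.0 if locus.gene_strand == "+" else -1.0
    return (x.midpoint - locus.tss) * sign


@dataclass(frozen=True)
class Amplicon:
    interval: GenomicInterval
    sequence: str


@dataclass(frozen=True)
class PcrResult:
    """All products of an in-silico PCR; ``ambiguous`` flags >1 product."""

    amplicons: tuple[Amplicon, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.amplicons) > 1

    def __bool__(self) -> bool:
        return len(self.amplicons) > 0


def insilico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    chrom: str = "template",
    origin: int = 1,
) -> PcrResult:
    """Exact-match in-silico PCR on the plus strand of ``template``.

    The forward primer must match the template verbatim; the reverse primer's
    reverse complement must match downstream of (or overlapping past) the
    forward match.  Windows containing ``N`` never match.  Every product is
    returned; more than one is flagged as ambiguous, not raised.
    """
    for name, p in (("forward", fwd_primer), ("reverse", rev_primer)):
        if len(p) < 15:
            raise ValueError(f"{name} primer shorter than 15 nt")
    seq = template.upper()
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer.upper())

    def clean_hits(pattern: str) -> list[int]:
        if "N" in pattern:
            return []
        return [p for p in find_sites(seq, pattern) if "N" not in seq[p : p + len(pattern)]]

    products = []
    for f in clean_hits(fwd):
        for r in clean_hits(rev_rc):
            r_end = r + len(rev_rc)  # exclusive
            if r_end > f and r >= f:  # reverse site begins at/after forward start
                iv = GenomicInterval(chrom, origin + f, origin + r_end - 1)
                products.append(Amplicon(iv, seq[f:r_end]))
    return PcrResult(tuple(products))


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA reader (gzip-aware); sequences uppercased."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def interval_to_bed_fields(iv: GenomicInterval) -> tuple[str, int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return iv.chrom, iv.start - 1, iv.end


def interval_from_bed_fields(chrom: str, start: int, end: int, strand: str = ".") -> GenomicInterval:
    """BED 0-based half-open -> 1-based inclusive."""
    return GenomicInterval(chrom, start + 1, end, strand)


def write_fragment_bed(path: str | Path, fragments: Sequence[RestrictionFragment]) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            chrom, start, end = interval_to_bed_fields(frag.interval)
            fh.write(f"{chrom}\t{start}\t{end}\tfrag_{frag.index}\n")


def read_fragment_bed(path: str | Path) -> list[RestrictionFragment]:
    frags = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            iv = interval_from_bed_fields(fields[0], int(fields[1]), int(fields[2]))
            frags.append(RestrictionFragment(iv, index=k))
    return frags


def fragments_to_table(fragments: Sequence[RestrictionFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [f.interval.chrom for f in fragments],
            "start": [f.interval.start for f in fragments],
            "end": [f.interval.end for f in fragments],
            "index": [f.index for f in fragments],
        }
    )


def write_fragment_table(path: str | Path, fragments: Sequence[RestrictionFragment]) -> None:
    fragments_to_table(fragments).to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> list[RestrictionFragment]:
    df = pd.read_csv(path, sep="\t")
    return [
        RestrictionFragment(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.index))
        for r in df.itertuples()
    ]
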