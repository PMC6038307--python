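"""Turn 5C sequencing reads into per-library interaction-frequency lists (IFLs).

A 5C read is a ligation junction: the forward primer's genomic sequence
immediately followed by the reverse primer's genomic sequence, optionally
still carrying the universal amplification tails.  Counting therefore reduces
to demultiplexing each read against the (forward, reverse) primer pairs of the
design, with a small per-segment substitution tolerance.

Ambiguity is handled conservatively: a read whose best-scoring assignment is
shared by two or more primer pairs is discarded as unassigned rather than
randomly attributed.  Only forward x reverse pairs are countable — the
ligation-mediated amplification chemistry cannot join two primers of the same
orientation — so anything else lands in the unassigned tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gzip

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome_model import reverse_complement
from .primer_design import A_KEY_TAIL, P1_KEY_TAIL, FiveCDesign


@dataclass(frozen=True)
class ContactCount:
    forward_primer_id: str
    reverse_primer_id: str
    raw_count: int


@dataclass
class IFL:
    """Interaction-frequency list: read counts per (forward, reverse) contact."""

    library_id: str
    counts: dict[tuple[str, str], int]
    total_run_reads: int
    unassigned_reads: int
    unassigned_by_reason: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assigned = sum(self.counts.values())
        if assigned + self.unassigned_reads != self.total_run_reads:
            raise ValueError(
                f"count conservation violated: {assigned} assigned + "
                f"{self.unassigned_reads} unassigned != {self.total_run_reads} reads"
            )

    @property
    def contacts(self) -> list[ContactCount]:
        return [ContactCount(f, r, c) for (f, r), c in self.counts.items()]


@dataclass(frozen=True)
class ContactAssignment:
    forward_primer_id: str
    reverse_primer_id: str
    mismatches: int


@dataclass(frozen=True)
class Unassigned:
    reason: str  # too_short | no_match | ambiguous


def _hamming_leq(a: str, b: str, limit: int) -> int | None:
    """Hamming distance of equal-length strings if <= limit, else None."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return None
    return d


class _DesignIndex:
    """Lookup structures for fast read assignment against one design."""

    def __init__(self, design: FiveCDesign) -> None:
        self.design = design
        self.forwards = design.forward_primers
        self.reverses = design.reverse_primers
        self.valid = set(design.valid_pairs())
        self.exact_fwd = {p.genomic_seq: p for p in self.forwards}
        self.exact_rev = {p.genomic_seq: p for p in self.reverses}
        self.fwd_lengths = sorted({len(p.genomic_seq) for p in self.forwards})
        self.min_junction = (
            min((len(p.genomic_seq) for p in self.forwards), default=0)
            + min((len(p.genomic_seq) for p in self.reverses), default=0)
        )


def _strip_tails(read: str) -> str:
    if read.startswith(A_KEY_TAIL):
        read = read[len(A_KEY_TAIL) :]
    if read.endswith(P1_KEY_TAIL):
        read = read[: -len(P1_KEY_TAIL)]
    return read


def _match_oriented(read: str, idx: _DesignIndex, max_mismatch: int):
    """Best (fwd, rev, mismatches) assignments of one read orientation."""
    # exact fast path; a 0-mismatch hit always dominates
    exact_hits: list[tuple[str, str, int]] = []
    for lf in idx.fwd_lengths:
        fwd = idx.exact_fwd.get(read[:lf])
        if fwd is None:
            continue
        rest = read[lf:]
        for rev in idx.reverses:
            lr = len(rev.genomic_seq)
            if len(rest) >= lr and rest[:lr] == rev.genomic_seq:
                if (fwd.id, rev.id) in idx.valid:
                    exact_hits.append((fwd.id, rev.id, 0))
    if exact_hits:
        return exact_hits
    if max_mismatch == 0:
        return []
    best = max_mismatch * 2 + 1
    hits: list[tuple[str, str, int]] = []
    for fwd in idx.forwards:
        lf = len(fwd.genomic_seq)
        if len(read) < lf:
            continue
        df = _hamming_leq(read[:lf], fwd.genomic_seq, max_mismatch)
        if df is None:
            continue
        for rev in idx.reverses:
            if (fwd.id, rev.id) not in idx.valid:
                continue
            lr = len(rev.genomic_seq)
            if len(read) < lf + lr:
                continue
            dr = _hamming_leq(read[lf : lf + lr], rev.genomic_seq, max_mismatch)
            if dr is None:
                continue
            total = df + dr
            if total < best:
                best = total
                hits = [(fwd.id, rev.id, total)]
            elif total == best:
                hits.append((fwd.id, rev.id, total))
    return hits


def match_read(
    read: str,
    design: FiveCDesign | _DesignIndex,
    max_mismatch: int = 2,
    scan_reverse_complement: bool = True,
) -> ContactAssignment | Unassigned:
    """Assign one read to a (forward, reverse) primer pair, or explain why not.

    The universal tails are stripped if present; each primer segment may carry
    at most ``max_mismatch`` substitutions; ties at the best total mismatch
    count across pairs (and across the two read orientations) are discarded.
    """
    idx = design if isinstance(design, _DesignIndex) else _DesignIndex(design)
    read = read.upper()
    candidates = []
    for oriented in ([read, reverse_complement(read)] if scan_reverse_complement else [read]):
        stripped = _strip_tails(oriented)
        if len(stripped) < idx.min_junction:
            continue
        candidates.extend(_match_oriented(stripped, idx, max_mismatch))
    if len(_strip_tails(read)) < idx.min_junction and not candidates:
        return Unassigned("too_short")
    if not candidates:
        return Unassigned("no_match")
    best = min(c[2] for c in candidates)
    winners = {(f, r) for f, r, d in candidates if d == best}
    if len(winners) > 1:
        return Unassigned("ambiguous")
    f, r = next(iter(winners))
    return ContactAssignment(f, r, best)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """(title, sequence, quality) triples from a FASTQ(.gz) file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        yield from FastqGeneralIterator(fh)


def count_junctions(
    reads: str | Path | Iterable[str],
    design: FiveCDesign,
    max_mismatch: int = 2,
    library_id: str = "library",
    scan_reverse_complement: bool = True,
) -> IFL:
    """Aggregate :func:`match_read` over a FASTQ file (or iterable of sequences).

    Every valid (forward, reverse) pair of the design appears in the output,
    zero-filled if unseen; assigned + unassigned always equals the number of
    reads.  Malformed FASTQ records raise with the failing record number.
    """
    idx = _DesignIndex(design)
    counts: dict[tuple[str, str], int] = {pair: 0 for pair in design.valid_pairs()}
    unassigned: dict[str, int] = {}
    total = 0

    if isinstance(reads, (str, Path)):
        def _seqs() -> Iterator[str]:
            record_no = 0
            try:
                for _title, seq, _qual in iter_fastq(reads):
                    record_no += 1
                    yield seq
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {record_no + 1}: {exc}") from exc

        seq_iter: Iterable[str] = _seqs()
    else:
        seq_iter = reads

    for seq in seq_iter:
        total += 1
        res = match_read(seq, idx, max_mismatch, scan_reverse_complement)
        if isinstance(res, ContactAssignment):
            counts[(res.forward_primer_id, res.reverse_primer_id)] += 1
        else:
            unassigned[res.reason] = unassigned.get(res.reason, 0) + 1

    return IFL(
        library_id=library_id,
        counts=counts,
        total_run_reads=total,
        unassigned_reads=sum(unassigned.values()),
        unassigned_by_reason=unassigned,
    )


def ifl_to_table(ifl: IFL) -> pd.DataFrame:
    rows = [
        {"library_id": ifl.library_id, "fwd_id": f, "rev_id": r, "raw_count": c}
        for (f, r), c in sorted(ifl.counts.items())
    ]
    return pd.DataFrame(rows, columns=["library_id", "fwd_id", "rev_id", "raw_count"])


def write_ifl(path: str | Path, ifl: IFL, summary_path: str | Path | None = None) -> None:
    ifl_to_table(ifl).to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write(f"library_id\t{ifl.library_id}\n")
            fh.write(f"total_run_reads\t{ifl.total_run_reads}\n")
            fh.write(f"unassigned_reads\t{ifl.unassigned_reads}\n")
            for reason, n in sorted(ifl.unassigned_by_reason.items()):
                fh.write(f"unassigned_{reason}\t{n}\n")


def read_ifl(path: str | Path, total_run_reads: int | None = None) -> IFL:
    df = pd.read_csv(path, sep="\t")
    counts = {(r.fwd_id, r.rev_id): int(r.raw_count) for r in df.itertuples()}
    lib = str(df["library_id"].iloc[0]) if len(df) else "library"
    assigned = sum(counts.values())
    total = assigned if total_run_reads is None else total_run_reads
    return IFL(lib, counts, total, total - assigned)
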