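"""Screening sequencing reads for spike-in fragments.

Reads are matched against the amplicon bodies with an exact k-mer seed and
Hamming extension (substitution-only error is assumed, so no general aligner
is needed).  Terminal barcodes are extracted at their expected offset and
decoded with single-error correction.  Hits are classed as

* ``intact``   — both termini of the tagged fragment observed (read 1 starts
  at the barcode, the mapped insert reaches the opposite terminus),
* ``broken``   — exactly one tagged terminus, the other end an internal
  breakpoint (the signature of a molecule cut during shearing),
* ``internal_only`` — amplicon-body match with no tagged terminus.

Per-sample summaries aggregate into the assurance matrix of library barcode
by spike-in barcode counts on which all downstream verdicts rest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .barcodes import BarcodeSet, decode_batch, decode_index, STATUS_PERFECT, STATUS_CORRECTED
from .spikein import AmpliconTemplate, revcomp

__all__ = [
    "ScreenConfig",
    "AmpliconIndex",
    "SASIHit",
    "ScreenSummary",
    "AssuranceMatrix",
    "classify_read",
    "screen_reads",
    "screen_experiment",
    "demultiplex_reads",
    "build_assurance_matrix",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Matching parameters.

    ``seed_kmer`` exact-match seeds anchor a candidate diagonal;
    ``max_mismatch_frac`` bounds the Hamming mismatch fraction of the
    extended alignment; ``terminal_slop`` is the bp tolerance when deciding
    whether an alignment reaches an amplicon terminus.
    """

    seed_kmer: int = 21
    seed_step: int = 7
    max_mismatch_frac: float = 0.1
    terminal_slop: int = 2
    max_correct: int = 1


@dataclass(frozen=True)
class SASIHit:
    read_id: str
    amplicon_name: str
    sasi_barcode_id: int | None
    match_class: str  # intact | broken | internal_only
    mismatches: int


class AmpliconIndex:
    """Precomputed k-mer index over the (untagged) amplicon bodies."""

    def __init__(
        self,
        amplicons: Sequence[AmpliconTemplate] | dict[str, AmpliconTemplate],
        barcode_set: BarcodeSet,
        tagging_mode: str = "forward_only",
        config: ScreenConfig = ScreenConfig(),
    ):
        amps = list(amplicons.values()) if isinstance(amplicons, dict) else list(amplicons)
        self.amplicons = {a.name: a for a in amps}
        self.barcode_set = barcode_set
        if tagging_mode not in ("forward_only", "both_ends"):
            raise ValueError(f"unknown tagging_mode {tagging_mode!r}")
        self.tagging_mode = tagging_mode
        self.config = config
        k = config.seed_kmer
        for a in amps:
            if a.length < k:
                raise ValueError(f"amplicon {a.name} shorter than the seed k-mer ({k})")
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for a in amps:
            for pos in range(a.length - k + 1):
                self.kmers.setdefault(a.sequence[pos : pos + k], []).append((a.name, pos))


def _extend(read: str, amp: str, diag: int) -> tuple[int, int, int]:
    """Hamming-compare read against amplicon along a fixed diagonal.

    ``diag`` is the amplicon position aligned with read position 0 (may be
    negative when the read starts upstream of the amplicon, i.e. in the
    barcode).  Returns (amp_start, overlap_length, mismatches) for the
    overlapping region.
    """
    a0 = max(0, diag)
    r0 = a0 - diag
    length = min(len(read) - r0, len(amp) - a0)
    if length <= 0:
        return a0, 0, 0
    mism = sum(1 for x, y in zip(read[r0 : r0 + length], amp[a0 : a0 + length]) if x != y)
    return a0, length, mism


def _best_alignment(read: str, index: AmpliconIndex) -> tuple[str, int, int, int] | None:
    """Seed-and-extend one read (already in amplicon orientation).

    Returns (amplicon_name, diag, overlap, mismatches) for the first seed
    diagonal whose extension passes the mismatch bound, preferring lower
    mismatch counts among candidate diagonals of the same seed scan.
    """
    cfg = index.config
    k = cfg.seed_kmer
    if len(read) < k:
        return None
    best = None
    tried: set[tuple[str, int]] = set()
    for off in range(0, len(read) - k + 1, cfg.seed_step):
        hits = index.kmers.get(read[off : off + k])
        if not hits:
            continue
        for name, pos in hits:
            diag = pos - off
            if (name, diag) in tried:
                continue
            tried.add((name, diag))
            amp = index.amplicons[name].sequence
            a0, overlap, mism = _extend(read, amp, diag)
            if overlap >= k and mism <= cfg.max_mismatch_frac * overlap:
                if best is None or mism < best[3]:
                    best = (name, diag, overlap, mism)
        if best is not None and best[3] == 0:
            break
    return best


def _orient(read: str, index: AmpliconIndex) -> tuple[str, tuple[str, int, int, int]] | None:
    """Try the read and its reverse complement; return the oriented sequence
    and its alignment."""
    aln = _best_alignment(read, index)
    if aln is not None:
        return read, aln
    rc = revcomp(read)
    aln = _best_alignment(rc, index)
    if aln is not None:
        return rc, aln
    return None


def _terminal_evidence(
    oriented: str, aln: tuple[str, int, int, int], index: AmpliconIndex
) -> tuple[bool, int | None, bool]:
    """From one oriented aligned read, extract (forward_terminus,
    decoded_barcode_id, reverse_terminus)."""
    cfg = index.config
    name, diag, overlap, _ = aln
    amp = index.amplicons[name]
    L = index.barcode_set.length
    a0 = max(0, diag)
    fwd = False
    barcode_id: int | None = None
    if a0 <= cfg.terminal_slop:
        # alignment reaches the amplicon 5' start; the barcode should sit
        # immediately upstream in the read
        r_origin = a0 - diag  # read position of amplicon position a0
        bc_end = r_origin - a0
        if bc_end - L >= 0:
            fwd = True
            res = decode_index(
                oriented[bc_end - L : bc_end], index.barcode_set, cfg.max_correct
            )
            if res.status in ("perfect", "corrected"):
                barcode_id = res.barcode_id
    rev = a0 + overlap >= amp.length - cfg.terminal_slop
    return fwd, barcode_id, rev


def classify_read(
    read1: str,
    read2: str | None,
    index: AmpliconIndex,
    read_id: str = "",
) -> SASIHit | None:
    """Classify a read (or pair) against the spike-in amplicons.

    Returns None when neither read matches any amplicon body.  With a pair,
    terminus evidence from both mates is combined: a fragment is intact when
    the tagged 5' terminus (with a decodable barcode) and the opposite
    terminus are both observed.
    """
    o1 = _orient(read1, index)
    o2 = _orient(read2, index) if read2 else None
    if o1 is None and o2 is None:
        return None
    fwd = False
    rev = False
    barcode_id: int | None = None
    names = []
    mism = 0
    for o in (o1, o2):
        if o is None:
            continue
        oriented, aln = o
        names.append(aln[0])
        mism += aln[3]
        f, bid, r = _terminal_evidence(oriented, aln, index)
        fwd = fwd or f
        rev = rev or r
        if bid is not None and barcode_id is None:
            barcode_id = bid
    # prefer the amplicon identified by read 1 when mates disagree (nested
    # amplicon designs make interior matches ambiguous); reverse-end-only
    # hits keep the amplicon name with barcode absent
    name = names[0]
    if fwd and barcode_id is not None and rev:
        match_class = "intact"
    elif fwd or rev:
        match_class = "broken"
    else:
        match_class = "internal_only"
    return SASIHit(read_id, name, barcode_id, match_class, mism)


@dataclass
class ScreenSummary:
    """Per-sample screening outcome."""

    sample_id: str
    total_reads: int = 0
    sasi_reads: int = 0
    counts: Counter = field(default_factory=Counter)  # (barcode_id|0, amplicon, class)

    @property
    def spikein_fraction(self) -> float:
        return self.sasi_reads / self.total_reads if self.total_reads else 0.0

    def barcode_counts(self) -> Counter:
        """Spike-in read counts per decoded barcode id (0 = no barcode)."""
        out: Counter = Counter()
        for (bid, _amp, _cls), n in self.counts.items():
            out[bid] += n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.sample_id, bid, amp, cls, n)
            for (bid, amp, cls), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample", "sasi_barcode", "amplicon", "match_class", "count"]
        )


def screen_reads(
    sample_id: str,
    reads: Iterable[tuple[str, str, str | None]],
    index: AmpliconIndex,
) -> ScreenSummary:
    """Screen an iterable of (read_id, read1, read2-or-None); streaming,
    memory use independent of read count."""
    summary = ScreenSummary(sample_id)
    for rid, r1, r2 in reads:
        summary.total_reads += 1
        hit = classify_read(r1, r2, index, rid)
        if hit is not None:
            summary.sasi_reads += 1
            key = (hit.sasi_barcode_id or 0, hit.amplicon_name, hit.match_class)
            summary.counts[key] += 1
    return summary


def screen_experiment(result, index: AmpliconIndex) -> list[ScreenSummary]:
    """Screen every demultiplexed tube of a simulated experiment."""
    summaries = []
    for tube, batch in result.batches.items():
        r2 = batch.r2 if batch.r2 is not None else [None] * len(batch)
        summaries.append(
            screen_reads(tube, zip(batch.read_ids, batch.r1, r2), index)
        )
    return summaries


def demultiplex_reads(
    records: Iterable[tuple[str, str, str | None, str]],
    library_set: BarcodeSet,
    sample_of_barcode: dict[int, str],
    max_correct: int = 1,
    chunk: int = 50_000,
) -> Iterator[tuple[str, str, str, str | None]]:
    """Assign multiplexed (read_id, r1, r2, index_read) records to samples by
    decoding the index read with bounded-radius correction.

    Yields (sample_id, read_id, r1, r2); reads whose index does not decode,
    or decodes to a barcode absent from the mapping, go to sample
    ``"unassigned"``.
    """
    buf: list[tuple[str, str, str | None, str]] = []

    def flush(buf):
        status, bids, _ = decode_batch([b[3] for b in buf], library_set, max_correct)
        ok = (status == STATUS_PERFECT) | (status == STATUS_CORRECTED)
        for (rid, r1, r2, _idx), good, bid in zip(buf, ok, bids):
            sample = sample_of_barcode.get(int(bid), "unassigned") if good else "unassigned"
            yield sample, rid, r1, r2

    for rec in records:
        buf.append(rec)
        if len(buf) >= chunk:
            yield from flush(buf)
            buf = []
    if buf:
        yield from flush(buf)


@dataclass
class AssuranceMatrix:
    """Counts of spike-in reads per (sample row x spike-in barcode column).

    Column 0 collects spike-in reads whose terminal barcode could not be
    decoded (broken reverse-end or internal-only hits); identity verdicts
    ignore it, conservation checks include it.
    """

    table: pd.DataFrame  # index: sample ids; columns: barcode ids (int)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def row_margin(self, sample: str) -> int:
        return int(self.table.loc[sample].sum())

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssuranceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = df.columns.astype(int)
        return cls(df)


def build_assurance_matrix(summaries: Sequence[ScreenSummary]) -> AssuranceMatrix:
    """Tabulate spike-in barcode counts per sample.

    The matrix total equals the summed spike-in read counts of all samples.
    """
    ids = [s.sample_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in screen summaries")
    cols: set[int] = set()
    per_sample = {}
    for s in summaries:
        bc = s.barcode_counts()
        per_sample[s.sample_id] = bc
        cols.update(bc)
    columns = sorted(cols)
    table = pd.DataFrame(0, index=ids, columns=columns, dtype=np.int64)
    for sid, bc in per_sample.items():
        for bid, n in bc.items():
            table.loc[sid, bid] = n
    return AssuranceMatrix(table)
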