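"""Quality-control stage: drop sequencing artifacts and variation-explained pairs.

Unmapped pairs are adapter-clipped, quality-trimmed with a sliding window, and
length-filtered; half-mapped pairs whose unmapped mate is explained by a single
structural breakpoint near the anchored mate (a simplified anchored split-read
search, standing in for a full split-read caller) are set aside as
``variation``. Every input pair ends in exactly one outcome class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kmers
from ._align import scan_placements
from .formats import Anchor, ReadPair, SequenceRecord, revcomp

# Illumina TruSeq read-through adapters (R1 / R2)
TRUSEQ_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
TRUSEQ_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"
DEFAULT_ADAPTERS = (TRUSEQ_R1, TRUSEQ_R2)


@dataclass(frozen=True)
class QcParams:
    """Tunables of the QC stage.

    window/quality_threshold follow the 25nt / phred-25 sliding-window rule;
    min_length_fraction is the strict "both mates longer than half the
    expected read length" cut.
    """

    window: int = 25
    quality_threshold: float = 25.0
    min_length_fraction: float = 0.5
    adapters: tuple[str, ...] = DEFAULT_ADAPTERS
    min_adapter_overlap: int = 10
    mismatches_per_10bp: int = 0
    # breakpoint rescue of half-mapped pairs
    search_radius: Optional[int] = None  # default: 2 x expected fragment mean
    rescue_max_mismatch_per_half: int = 2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 <= self.quality_threshold <= 41):
            raise ValueError("quality_threshold must be in [0, 41]")
        if not (0 < self.min_length_fraction <= 1):
            raise ValueError("min_length_fraction must be in (0, 1]")


@dataclass
class QcOutcome:
    pair: ReadPair
    verdict: str  # pass | low_qc | variation
    variation_kind: Optional[str] = None


@dataclass
class QcSummary:
    """Counts of the QC partition; conserved: input = passed + low_qc + variation."""

    input: int = 0
    passed: int = 0
    low_qc: int = 0
    variation: int = 0


def clip_adapters(
    read: SequenceRecord,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    min_overlap: int = 5,
    mismatches_per_10bp: int = 0,
) -> SequenceRecord:
    """Remove the longest read suffix matching an adapter prefix.

    A suffix starting at position p matches when its overlap with the adapter
    (``min(len(read)-p, len(adapter))`` bases, which must be at least
    ``min_overlap``) agrees with the adapter prefix allowing
    ``mismatches_per_10bp * floor(overlap/10)`` mismatches (default exact).
    Everything from p onward is removed, quality in step. Clipping is repeated
    until stable so the operation is idempotent.
    """
    seq, qual = read.sequence, read.quality
    while True:
        cut = _find_adapter_cut(seq, adapters, min_overlap, mismatches_per_10bp)
        if cut is None:
            break
        seq = seq[:cut]
        qual = qual[:cut] if qual is not None else None
    if seq == read.sequence:
        return read
    return SequenceRecord(read.id, seq, qual)


def _find_adapter_cut(
    seq: str, adapters: Sequence[str], min_overlap: int, per10: int
) -> Optional[int]:
    best: Optional[int] = None
    n = len(seq)
    for adapter in adapters:
        limit = n - min_overlap  # last start position with enough overlap
        if limit < 0:
            continue
        if per10 == 0:
            probe = adapter[:min_overlap]
            p = seq.find(probe)
            while 0 <= p <= limit:
                ov = min(n - p, len(adapter))
                if seq[p : p + ov] == adapter[:ov]:
                    if best is None or p < best:
                        best = p
                    break
                p = seq.find(probe, p + 1)
        else:
            for p in range(0, limit + 1):
                ov = min(n - p, len(adapter))
                allowed = per10 * (ov // 10)
                mm = sum(
                    1 for a, b in zip(seq[p : p + ov], adapter[:ov]) if a != b
                )
                if mm <= allowed:
                    if best is None or p < best:
                        best = p
                    break
    return best


def quality_trim(
    read: SequenceRecord, window: int = 25, threshold: float = 25.0
) -> SequenceRecord:
    """Sliding-window quality clipping (phred33).

    Scanning 5'→3', the read is cut at the first position opening a window of
    ``window`` bases (shrinking at the read end) whose mean quality falls
    below ``threshold``; bases before the cut are retained. Because
    truncation shortens the terminal windows, the scan is re-applied until the
    result is stable, making the operation idempotent.
    """
    if read.quality is None:
        raise ValueError(f"read {read.id!r} has no quality string")
    q = np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8).astype(
        np.float64
    ) - 33.0
    n = len(q)
    while n > 0:
        cut = _first_failing_window(q[:n], window, threshold)
        if cut is None:
            break
        n = cut
    if n == len(read.sequence):
        return read
    return SequenceRecord(read.id, read.sequence[:n], read.quality[:n])


def _first_failing_window(q: np.ndarray, window: int, threshold: float) -> Optional[int]:
    n = len(q)
    cs = np.concatenate(([0.0], np.cumsum(q)))
    starts = np.arange(n)
    ends = np.minimum(starts + window, n)
    means = (cs[ends] - cs[starts]) / (ends - starts)
    fail = np.nonzero(means < threshold)[0]
    return int(fail[0]) if fail.size else None


def length_ok(pair: ReadPair, min_length_fraction: float = 0.5) -> bool:
    """True iff both mates are strictly longer than the fraction of the
    expected read length (a mate at exactly the boundary fails)."""
    cut = min_length_fraction * pair.expected_read_length
    return len(pair.mate1) > cut and len(pair.mate2) > cut


# ---------------------------------------------------------------------------
# Variation rescue (anchored split search)
# ---------------------------------------------------------------------------

def rescue_variation(
    half_mapped: Sequence[tuple[ReadPair, Anchor]],
    primary_reference: Sequence[SequenceRecord],
    params: QcParams = QcParams(),
) -> list[Optional[str]]:
    """Classify half-mapped pairs as breakpoint-explained or not.

    The unmapped mate is split into two halves; each half is searched exactly
    (allowing ``rescue_max_mismatch_per_half`` mismatches) on both strands
    within the anchor interval padded by ``search_radius``. The pair is
    ``variation`` when the two halves place consistently with one breakpoint:

    * deletion — same strand, positive gap between the halves;
    * insertion — same strand, halves adjacent on the read but with
      overlapping placements;
    * tandem duplication — the downstream half places upstream of the first;
    * inversion — halves place on opposite strands.

    A contiguous placement (zero gap) means no breakpoint: the pair is left
    unrescued. Returns one kind (or None) per input pair, in order.
    """
    refs = {rec.id: _kmers.encode(rec.sequence) for rec in primary_reference}
    out: list[Optional[str]] = []
    for pair, anchor in half_mapped:
        if anchor.interval.seq_id not in refs:
            raise ValueError(
                f"anchor sequence {anchor.interval.seq_id!r} not in primary reference"
            )
        ref = refs[anchor.interval.seq_id]
        if anchor.interval.end > len(ref):
            raise ValueError(
                f"anchor {anchor.interval} outside reference "
                f"({anchor.interval.seq_id} has length {len(ref)})"
            )
        radius = params.search_radius
        if radius is None:
            mean = pair.expected_fragment[0]
            radius = int(2 * mean) if mean else 1000
        lo = max(0, anchor.interval.start - radius)
        hi = min(len(ref), anchor.interval.end + radius)
        window = ref[lo:hi]
        mate = pair.mate2 if anchor.mapped_mate == 1 else pair.mate1
        out.append(
            _breakpoint_kind(
                mate.sequence, window, params.rescue_max_mismatch_per_half
            )
        )
    return out


def _breakpoint_kind(seq: str, window: np.ndarray, max_mm: int) -> Optional[str]:
    if len(seq) < 4:
        return None
    kinds: set[str] = set()
    contiguous = False
    for oriented in (seq, revcomp(seq)):
        codes = _kmers.encode(oriented)
        half = len(codes) // 2
        h1, h2 = codes[:half], codes[half:]
        p1s = scan_placements(h1, window, max_mm)
        p2s = scan_placements(h2, window, max_mm)
        p1s_rc = scan_placements(_kmers.revcomp_codes(h1), window, max_mm)
        p2s_rc = scan_placements(_kmers.revcomp_codes(h2), window, max_mm)
        for p1 in p1s:
            for p2 in p2s:
                gap = p2 - (p1 + half)
                if gap == 0:
                    contiguous = True
                elif gap > 0:
                    kinds.add("deletion")
                elif p2 > p1:
                    kinds.add("insertion")
                else:
                    kinds.add("tandem_duplication")
        if (p1s and p2s_rc) or (p1s_rc and p2s):
            kinds.add("inversion")
    if contiguous:
        return None
    for kind in ("deletion", "insertion", "tandem_duplication", "inversion"):
        if kind in kinds:
            return kind
    return None


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def qc_pair(pair: ReadPair, params: QcParams = QcParams()) -> ReadPair:
    """Adapter-clip then quality-trim both mates of a pair."""
    mates = []
    for mate in (pair.mate1, pair.mate2):
        mate = clip_adapters(
            mate, params.adapters, params.min_adapter_overlap, params.mismatches_per_10bp
        )
        mate = quality_trim(mate, params.window, params.quality_threshold)
        mates.append(mate)
    return replace(pair, mate1=mates[0], mate2=mates[1])


def run_qc(
    pairs: Iterable[ReadPair],
    half_mapped: Sequence[tuple[ReadPair, Anchor]] = (),
    params: QcParams = QcParams(),
    primary_reference: Sequence[SequenceRecord] = (),
) -> tuple[list[ReadPair], QcSummary]:
    """Run the full QC stage: clip → trim → length rule → variation rescue.

    Returns the passing pairs (half-mapped pairs that were neither dropped nor
    rescued continue in the pipeline) and the outcome counts. Conservation:
    ``input == passed + low_qc + variation``.
    """
    summary = QcSummary()
    passing: list[ReadPair] = []

    for pair in pairs:
        summary.input += 1
        trimmed = qc_pair(pair, params)
        if length_ok(trimmed, params.min_length_fraction):
            summary.passed += 1
            passing.append(trimmed)
        else:
            summary.low_qc += 1

    surviving: list[tuple[ReadPair, Anchor]] = []
    for pair, anchor in half_mapped:
        summary.input += 1
        trimmed = qc_pair(pair, params)
        if length_ok(trimmed, params.min_length_fraction):
            surviving.append((trimmed, anchor))
        else:
            summary.low_qc += 1
    if surviving:
        kinds = rescue_variation(surviving, primary_reference, params)
        for (pair, _anchor), kind in zip(surviving, kinds):
            if kind is not None:
                summary.variation += 1
            else:
                summary.passed += 1
                passing.append(pair)

    return passing, summary
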