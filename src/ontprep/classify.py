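"""Read classification, reorientation, trimming and quality filtering.

With fitted cutoffs in hand, every read is processed as follows. The tuned
AP substring is aligned on both strands at each end; a hit passing the
similarity cutoff AND lying within the location cutoff of its expected
terminus is an accepted end hit, while a hit passing similarity but failing
location is a mid-read hit — evidence of a chimera (an AP in the middle of a
read means two amplicons were joined). Labels:

* chimeric    — any mid-read hit (takes precedence);
* full_length — front and rear end hits accepted, same strand, in order;
* truncated   — everything else (at most one usable end hit).

Full-length reads are reoriented to the sense strand, the APs and the
adjacent polyA tail are trimmed at the pinpointed AP/insert boundaries, and
mean Phred quality (computed in error-probability space) is filtered as the
very last step — after trimming, so low-quality terminal AP bases no longer
distort the read's quality estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .align import AlignmentHit, paired_hits
from .autotune import CutoffSet
from .schema import APSchema, AP_IDS, FRONT, REAR, end_distance
from .seqio import SequenceRecord, reverse_complement

DEFAULT_MIN_QUALITY = 7.0

FULL_LENGTH = "full_length"
TRUNCATED = "truncated"
CHIMERIC = "chimeric"
FAILED_QUALITY = "failed_quality"

# polyA scan: anchored at the rear AP boundary, requires >= 4 adjacent A's,
# skips non-A runs of <= 2 bases only when flanked by an A and the scanned
# window stays >= 80% A.
POLYA_MIN_ANCHOR = 4
POLYA_MAX_GAP = 2
POLYA_MIN_FRACTION = 0.8


@dataclass
class APLocateResult:
    accepted: dict[str, AlignmentHit] = field(default_factory=dict)
    mid_hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class ReadClassification:
    read_id: str
    label: str
    strand: str  # "+", "-" or "unknown"
    front_hit: AlignmentHit | None = None
    rear_hit: AlignmentHit | None = None
    mid_hits: list[AlignmentHit] = field(default_factory=list)
    trim_interval: tuple[int, int] | None = None  # on the oriented read
    mean_q_after_trim: float | None = None
    passes_quality: bool | None = None


def locate_aps(read: SequenceRecord, schema: APSchema,
               cutoffs: Mapping[str, CutoffSet]) -> APLocateResult:
    """Align tuned AP substrings on both strands and screen the hits.

    For each AP end the first (best) hit per strand and the masked second hit
    are screened: similarity-and-location passers become accepted end hits
    (best strand kept), similarity-only passers are mid-read hits. Screening
    the masked second alignment catches internal AP copies even when the best
    hit sits at a read end. Reads shorter than the tuned substring yield no
    hits at that end.
    """
    result = APLocateResult()
    n = len(read)
    for ap_id in AP_IDS:
        cut = cutoffs[ap_id]
        accepted_candidates: list[AlignmentHit] = []
        for strand in ("+", "-"):
            pattern = schema.pattern(ap_id, strand, cut.ap_sub_length)
            first, second = paired_hits(pattern, read.sequence, ap_id, strand)
            for hit in (first, second):
                if hit is None or hit.similarity < cut.similarity_cutoff:
                    continue
                dist = end_distance(ap_id, strand, hit.read_start,
                                    hit.read_end, n)
                if dist > cut.location_cutoff:
                    result.mid_hits.append(hit)
                elif hit.rank == "first":
                    accepted_candidates.append(hit)
        if accepted_candidates:
            best = max(accepted_candidates,
                       key=lambda h: (h.similarity, h.strand == "+"))
            result.accepted[ap_id] = best
    return result


def _oriented(hit: AlignmentHit, read_length: int) -> tuple[int, int]:
    """Map a hit interval onto the sense-oriented read."""
    if hit.strand == "+":
        return hit.read_start, hit.read_end
    return read_length - hit.read_end, read_length - hit.read_start


def classify_read(read: SequenceRecord,
                  located: APLocateResult) -> ReadClassification:
    """Assign full_length / truncated / chimeric from located AP hits.

    Chimeric takes precedence. Full-length requires accepted front and rear
    hits on the same strand with the front interval preceding the rear on the
    oriented read; an inconsistent pair keeps only the better hit and the
    read is truncated. Truncated reads with one accepted hit still record
    strand.
    """
    n = len(read)
    front = located.accepted.get(FRONT)
    rear = located.accepted.get(REAR)
    if located.mid_hits:
        strand = front.strand if front else (rear.strand if rear else "unknown")
        return ReadClassification(read.read_id, CHIMERIC, strand,
                                  front_hit=front, rear_hit=rear,
                                  mid_hits=list(located.mid_hits))
    if front is not None and rear is not None:
        consistent = front.strand == rear.strand
        if consistent:
            f_start, f_end = _oriented(front, n)
            r_start, r_end = _oriented(rear, n)
            consistent = f_end <= r_start
        if consistent:
            return ReadClassification(read.read_id, FULL_LENGTH, front.strand,
                                      front_hit=front, rear_hit=rear)
        # keep only the better-supported end; the read is not full length
        if front.similarity >= rear.similarity:
            rear = None
        else:
            front = None
    hit = front if front is not None else rear
    strand = hit.strand if hit is not None else "unknown"
    return ReadClassification(read.read_id, TRUNCATED, strand,
                              front_hit=front, rear_hit=rear)


def _polya_trim_point(seq: str, boundary: int, start_limit: int) -> int:
    """Left edge of the polyA window ending at ``boundary``.

    Scans insert-ward from the rear-AP boundary. Requires POLYA_MIN_ANCHOR
    A's immediately at the boundary; skips interior non-A runs of at most
    POLYA_MAX_GAP bases when an A lies beyond them and the A-fraction of the
    whole scanned window stays >= POLYA_MIN_FRACTION. Returns ``boundary``
    unchanged when no polyA is anchored there.
    """
    if boundary - start_limit < POLYA_MIN_ANCHOR:
        return boundary
    anchor = seq[boundary - POLYA_MIN_ANCHOR:boundary]
    if anchor != "A" * POLYA_MIN_ANCHOR:
        return boundary
    i = boundary
    n_a = 0
    while i > start_limit:
        if seq[i - 1] == "A":
            i -= 1
            n_a += 1
            continue
        j = i
        while j > start_limit and seq[j - 1] != "A":
            j -= 1
        run = i - j
        window = boundary - j + 1  # through the first A beyond the run
        if (run <= POLYA_MAX_GAP and j > start_limit
                and (n_a + 1) / window >= POLYA_MIN_FRACTION):
            i = j - 1
            n_a += 1
        else:
            break
    return i


def trim_read(read: SequenceRecord, classification: ReadClassification,
              schema: APSchema) -> SequenceRecord:
    record, _ = trim_read_with_interval(read, classification, schema)
    return record


def trim_read_with_interval(read: SequenceRecord,
                            classification: ReadClassification,
                            schema: APSchema,
                            ) -> tuple[SequenceRecord, tuple[int, int]]:
    """Reorient a full-length read and cut out the insert.

    The read is reverse-complemented to sense orientation when the APs
    matched on the minus strand (qualities reversed in lockstep), then
    everything up to the front AP's insert-proximal boundary and from the
    rear AP's boundary outward is removed, and finally the polyA run anchored
    at the rear boundary is trimmed. The output is a contiguous subsequence
    of the oriented read; the original strand is recorded in the comment.
    """
    if classification.label != FULL_LENGTH:
        raise ValueError(
            f"trim_read requires a full_length read, got {classification.label}"
        )
    n = len(read)
    oriented = read if classification.strand == "+" else reverse_complement(read)
    _, front_end = _oriented(classification.front_hit, n)
    rear_start, _ = _oriented(classification.rear_hit, n)
    polya_start = _polya_trim_point(oriented.sequence, rear_start, front_end)
    interval = (front_end, polya_start)
    comment = f"strand={classification.strand}"
    if read.comment:
        comment = f"{read.comment} {comment}"
    record = SequenceRecord(
        read_id=read.read_id,
        sequence=oriented.sequence[front_end:polya_start],
        qualities=oriented.qualities[front_end:polya_start],
        comment=comment,
    )
    return record, interval


def mean_quality(record: SequenceRecord) -> float:
    """Mean Phred quality via mean error probability: -10 log10(mean 10^(-Q/10))."""
    if not record.qualities:
        raise ValueError("empty record has no mean quality")
    mean_p = sum(10 ** (-q / 10) for q in record.qualities) / len(record.qualities)
    return -10 * math.log10(mean_p)


@dataclass
class PreprocessResult:
    """Partitioned output streams plus the per-read classification table."""

    streams: dict[str, list[SequenceRecord]]
    table: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.streams.items()}


def classify_stream(reads: Iterable[SequenceRecord], schema: APSchema,
                    cutoffs: Mapping[str, CutoffSet],
                    min_q: float = DEFAULT_MIN_QUALITY,
                    ) -> Iterator[tuple[str, SequenceRecord, dict]]:
    """Yield (category, output record, table row) per input read, streaming.

    Every input read goes to exactly one category. Full-length reads are
    trimmed and sense-oriented; their mean quality is computed after trimming
    and reads below ``min_q`` divert to failed_quality. Truncated and
    chimeric reads pass through unmodified.
    """
    for read in reads:
        located = locate_aps(read, schema, cutoffs)
        cls = classify_read(read, located)
        row = {
            "read_id": read.read_id,
            "label": cls.label,
            "strand": cls.strand,
            "front_s": cls.front_hit.similarity if cls.front_hit else None,
            "rear_s": cls.rear_hit.similarity if cls.rear_hit else None,
            "trim_start": None,
            "trim_end": None,
            "mean_q": None,
        }
        if cls.label == FULL_LENGTH:
            record, interval = trim_read_with_interval(read, cls, schema)
            cls.trim_interval = interval
            row["trim_start"], row["trim_end"] = interval
            if len(record) == 0:
                # degenerate: APs adjacent, nothing left after trimming
                cls.passes_quality = False
                row["label"] = FULL_LENGTH
                yield FAILED_QUALITY, record, row
                continue
            q = mean_quality(record)
            cls.mean_q_after_trim = q
            row["mean_q"] = q
            cls.passes_quality = q >= min_q
            yield (FULL_LENGTH if cls.passes_quality else FAILED_QUALITY,
                   record, row)
        else:
            yield cls.label, read, row


def preprocess(reads: Iterable[SequenceRecord], schema: APSchema,
               cutoffs: Mapping[str, CutoffSet],
               min_q: float = DEFAULT_MIN_QUALITY) -> PreprocessResult:
    """Classify, reorient, trim and quality-filter a whole read set.

    Returns the four partitioned streams (full_length, truncated, chimeric,
    failed_quality) and the classification table; counts are conserved.
    """
    streams: dict[str, list[SequenceRecord]] = {
        FULL_LENGTH: [], TRUNCATED: [], CHIMERIC: [], FAILED_QUALITY: [],
    }
    rows = []
    for category, record, row in classify_stream(reads, schema, cutoffs, min_q):
        streams[category].append(record)
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["read_id", "label", "strand", "front_s", "rear_s",
                       "trim_start", "trim_end", "mean_q"])
    return PreprocessResult(streams=streams, table=table)
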