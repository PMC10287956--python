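"""Overlap-merging of paired-end amplicon reads.

Amplicons are shorter than twice the read length, so the 150-bp read
pairs overlap and can be merged into one full-length fragment before
alignment — this is what makes large Cas9 deletions alignable.  The
merger scans every candidate relative placement of read 2 against read 1
(including "outie"/dovetail geometry, where the fragment is shorter than
the reads), scores each by mismatch density over the overlap, and keeps
the best placement if its density does not exceed the configured
maximum.

Defaults mirror common amplicon practice: minimum overlap 10 bp, maximum
mismatch density 10%, outies allowed, fragment-length SD 40 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .region import revcomp


@dataclass(frozen=True)
class MergeParams:
    """Settings for overlap merging.

    ``expected_fragment`` (typically the amplicon length) breaks ties
    between equally clean overlaps toward the placement whose implied
    fragment length is closest; ``None`` falls back to preferring the
    longer overlap.
    """

    min_overlap: int = 10
    max_mismatch_density: float = 0.10
    expected_fragment: Optional[int] = None
    fragment_sd: int = 40
    allow_outies: bool = True

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_density <= 1.0):
            raise ValueError("max_mismatch_density must be in [0, 1]")


@dataclass(frozen=True)
class MergedRead:
    """A merged fragment with per-base qualities and overlap diagnostics."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    overlap_len: int
    n_mismatches: int

    def __post_init__(self):
        assert len(self.sequence) == len(self.qualities)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_weight(a: np.ndarray, b: np.ndarray) -> float:
    """Mismatch count over two equal-length encoded segments.

    N bases (either side) count half: they are uninformative rather than
    contradictory, and full weight would discard otherwise good pairs.
    """
    n_code = ord("N")
    is_n = (a == n_code) | (b == n_code)
    hard = np.count_nonzero((a != b) & ~is_n)
    return hard + 0.5 * np.count_nonzero(is_n)


def merge_pair(r1: tuple[str, str, str], r2: tuple[str, str, str],
               params: MergeParams = MergeParams()) -> Optional[MergedRead]:
    """Merge one read pair; return ``None`` when no acceptable overlap exists.

    Parameters
    ----------
    r1, r2
        ``(read_id, sequence, quality_string)`` with ``r2`` in sequencer
        orientation (it is reverse-complemented internally).
    params
        Overlap acceptance settings.

    Notes
    -----
    Read 2 (reverse-complemented) is placed at every shift ``s`` relative
    to read 1; the overlap is the doubly covered interval.  ``s >= 0`` is
    the normal "innie" geometry and the merged fragment is the union of
    the two reads; ``s < 0`` is the dovetail "outie" geometry (fragment
    shorter than the reads) and the merged fragment is trimmed to the
    doubly covered interval, since the single-covered tails there run
    into adapter.  At overlap disagreements the base with the higher
    quality wins; where the bases agree the maximum quality is kept.
    """
    rid, seq1, qual1 = r1
    _, seq2_raw, qual2_raw = r2
    seq2 = revcomp(seq2_raw.upper())
    qual2 = qual2_raw[::-1]
    seq1 = seq1.upper()
    n1, n2 = len(seq1), len(seq2)
    if min(n1, n2) < params.min_overlap:
        return None

    a1, a2 = _encode(seq1), _encode(seq2)
    q1 = np.frombuffer(qual1.encode("ascii"), dtype=np.uint8).astype(int) - 33
    q2 = (np.frombuffer(qual2.encode("ascii"), dtype=np.uint8).astype(int) - 33)

    lo_shift = -(n2 - params.min_overlap) if params.allow_outies else max(0, n1 - n2)
    best = None  # (density, frag_penalty, -overlap, s, mism)
    for s in range(lo_shift, n1 - params.min_overlap + 1):
        o_start, o_end = max(0, s), min(n1, s + n2)
        olen = o_end - o_start
        if olen < params.min_overlap:
            continue
        mism = _mismatch_weight(a1[o_start:o_end], a2[o_start - s:o_end - s])
        density = mism / olen
        if density > params.max_mismatch_density:
            continue
        frag = s + n2 if s >= 0 else olen  # implied fragment length
        if s >= 0:
            frag = max(frag, n1)
        frag_pen = (abs(frag - params.expected_fragment)
                    if params.expected_fragment is not None else 0)
        cand = (density, frag_pen, -olen, s, mism)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None

    _, _, _, s, mism = best
    o_start, o_end = max(0, s), min(n1, s + n2)
    if s >= 0:
        span_start, span_end = 0, max(n1, s + n2)
    else:  # outie: keep only the doubly covered interval
        span_start, span_end = o_start, o_end

    seq_out = []
    qual_out = []
    for p in range(span_start, span_end):
        in1 = 0 <= p < n1
        in2 = 0 <= p - s < n2
        if in1 and in2:
            b1, b2 = seq1[p], seq2[p - s]
            if b1 == b2:
                seq_out.append(b1)
                qual_out.append(max(q1[p], q2[p - s]))
            elif q1[p] >= q2[p - s]:
                seq_out.append(b1)
                qual_out.append(q1[p])
            else:
                seq_out.append(b2)
                qual_out.append(q2[p - s])
        elif in1:
            seq_out.append(seq1[p])
            qual_out.append(q1[p])
        else:
            seq_out.append(seq2[p - s])
            qual_out.append(q2[p - s])
    return MergedRead(rid, "".join(seq_out), tuple(qual_out),
                      overlap_len=o_end - o_start,
                      n_mismatches=math.ceil(mism) if mism % 1 else int(mism))


@dataclass
class MergeStats:
    total: int = 0
    merged: int = 0

    @property
    def fraction(self) -> float:
        return self.merged / self.total if self.total else float("nan")


def merge_fastq(r1_path, r2_path, out_path, params: MergeParams = MergeParams()) -> MergeStats:
    """Merge a FASTQ pair file-to-file; returns per-file merge statistics."""
    from Bio import SeqIO

    stats = MergeStats()
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2, \
            open(out_path, "w") as out:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            stats.total += 1
            merged = merge_pair(
                (rec1.id, str(rec1.seq), _qualstr(rec1)),
                (rec2.id, str(rec2.seq), _qualstr(rec2)), params)
            if merged is not None:
                stats.merged += 1
                out.write(f"@{merged.read_id}\n{merged.sequence}\n+\n"
                          f"{''.join(chr(q + 33) for q in merged.qualities)}\n")
    return stats


def merge_pairs(pairs: Iterable[tuple[tuple, tuple]],
                params: MergeParams = MergeParams()) -> Iterator[MergedRead]:
    """Merge an in-memory iterable of read pairs, yielding merged reads."""
    for r1, r2 in pairs:
        m = merge_pair(r1, r2, params)
        if m is not None:
            yield m


def _qualstr(rec) -> str:
    return "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])


def _open_maybe_gz(path):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip
        return gzip.open(path, "rt")
    return open(path)


def write_merge_stats(stats_by_file: dict[str, MergeStats], path) -> None:
    """Write a TSV of per-file merge statistics (total, merged, fraction)."""
    with open(path, "w") as fh:
        fh.write("file\ttotal\tmerged\tfraction\n")
        for name in sorted(stats_by_file):
            s = stats_by_file[name]
            fh.write(f"{name}\t{s.total}\t{s.merged}\t{s.fraction:.6f}\n")
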