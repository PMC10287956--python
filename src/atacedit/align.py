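"""Glocal alignment of merged reads to the amplicon reference.

Reads are aligned end-to-end (read-global) against any stretch of the
amplicon (reference-local) with affine gap penalties tuned so that a
single long Cas9-induced deletion is cheaper than a handful of
mismatches: with the defaults (match +4, mismatch −16, gap open 24,
extend 1 per base) a 100-bp deletion costs 124, less than 8 mismatches.
ATAC reads legitimately stop at the Tn5 insertion point mid-amplicon, so
the unaligned reference tail is never penalized.

The aligner itself is Biopython's :class:`Bio.Align.PairwiseAligner`;
this module owns the scoring convention, strand handling, conversion of
the optimal path to CIGAR/edit operations, and left-normalization of
indels so that every deletion has one canonical identity regardless of
where the optimizer happened to place it inside a repeat.

Externally aligned SAM/BAM files can be ingested instead via
:func:`load_alignments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from Bio import Align

from .region import AmpliconRegion, Edit, revcomp

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring (all penalties positive).

    A gap of length *k* costs ``gap_open + k * gap_extend``. ``min_score``
    is the minimum alignment score for a read to count as mapped.
    """

    match: int = 4
    mismatch: int = 16
    gap_open: int = 24
    gap_extend: int = 1
    min_score: int = 70

    def __post_init__(self):
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("all scoring parameters must be positive")


@dataclass
class Alignment:
    """One read aligned to the amplicon.

    ``cigar`` uses ops ``= X I D S`` with query-consuming ops summing to
    the read length; ``edit_ops`` is the canonical (left-normalized) list
    of differences from the reference in absolute amplicon offsets.
    """

    read_id: str
    ref_name: str
    ref_start: int
    cigar: list[tuple[str, int]]
    edit_ops: tuple[Edit, ...]
    mapped: bool
    score: float = 0.0
    strand: str = "+"
    query: str = ""
    quals: tuple[int, ...] = ()

    @property
    def ref_end(self) -> int:
        """One past the last reference offset consumed."""
        return self.ref_start + sum(n for op, n in self.cigar if op in "=XD")

    def reconstruct_query(self, ref_seq: str) -> str:
        """Rebuild the aligned read from the reference and ``edit_ops``."""
        out, pos = [], self.ref_start
        for e in sorted(self.edit_ops):
            out.append(ref_seq[pos:e.ref_offset])
            out.append(e.alt_bases)
            pos = e.ref_end
        out.append(ref_seq[pos:self.ref_end])
        return "".join(out)


def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = -scoring.mismatch
    # Biopython charges open+(k-1)*extend for a k-gap; shift so a k-gap
    # costs gap_open + k*gap_extend.
    a.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    a.extend_gap_score = -scoring.gap_extend
    a.end_deletion_score = 0  # unaligned reference flanks are free
    return a


def _path_to_ops(aln, ref_seq: str, read_seq: str):
    """Convert a Biopython alignment to (ref_start, cigar, raw edit ops)."""
    blocks_t, blocks_q = aln.aligned
    cigar: list[tuple[str, int]] = []
    ops: list[Edit] = []

    def push(op, n):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    ref_start = int(blocks_t[0][0])
    prev_t, prev_q = ref_start, int(blocks_q[0][0])
    if prev_q:  # leading read bases inserted before the first aligned block
        ops.append(Edit(ref_start, "", read_seq[:prev_q]))
        push("I", prev_q)
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        t0, t1, q0, q1 = map(int, (t0, t1, q0, q1))
        if t0 > prev_t:
            ops.append(Edit(prev_t, ref_seq[prev_t:t0], ""))
            push("D", t0 - prev_t)
        if q0 > prev_q:
            ops.append(Edit(t0, "", read_seq[prev_q:q0]))
            push("I", q0 - prev_q)
        for t, q in zip(range(t0, t1), range(q0, q1)):
            if ref_seq[t] == read_seq[q]:
                push("=", 1)
            else:
                ops.append(Edit(t, ref_seq[t], read_seq[q]))
                push("X", 1)
        prev_t, prev_q = t1, q1
    if prev_q < len(read_seq):  # trailing inserted read bases
        ops.append(Edit(prev_t, "", read_seq[prev_q:]))
        push("I", len(read_seq) - prev_q)
    return ref_start, cigar, ops


def left_normalize(ops: list[Edit], ref_seq: str, floor: int = 0) -> tuple[Edit, ...]:
    """Shift indels to their leftmost equivalent placement within repeats.

    Gives every deletion/insertion one canonical identity (the variant-
    normalization convention); ``floor`` bounds the shift to the aligned
    reference interval.
    """
    ops = sorted(ops)
    out: list[Edit] = []
    for i, e in enumerate(ops):
        if e.is_substitution:
            out.append(e)
            continue
        lo = floor
        if out:
            prev = out[-1]
            lo = max(lo, prev.ref_end + (1 if prev.is_insertion else 0))
        o = e.ref_offset
        seq = e.ref_bases if e.is_deletion else e.alt_bases
        while o > lo and ref_seq[o - 1] == seq[-1]:
            seq = ref_seq[o - 1] + seq[:-1]
            o -= 1
        if e.is_deletion:
            out.append(Edit(o, ref_seq[o:o + len(seq)], ""))
        else:
            out.append(Edit(o, "", seq))
    return tuple(sorted(out))


def align_read(read, region: AmpliconRegion,
               scoring: ScoringParams = ScoringParams(),
               try_reverse: bool = True) -> Alignment:
    """Align one merged read to the amplicon reference.

    ``read`` is a :class:`~atacedit.merge.MergedRead` or an
    ``(id, sequence, qualities)`` tuple (qualities as a phred string or
    integer sequence).  Both orientations are tried and the higher-scoring
    one kept, so classification is orientation-invariant.

    Raises
    ------
    ValueError
        If the read is empty or contains non-IUPAC characters.
    """
    rid, seq, quals = _as_read(read)
    if not seq:
        raise ValueError(f"read {rid!r} is empty")
    if set(seq) - _VALID:
        raise ValueError(
            f"read {rid!r} contains non-ACGTN characters: "
            f"{sorted(set(seq) - _VALID)}")

    aligner = _make_aligner(scoring)
    candidates = [("+", seq, quals)]
    if try_reverse:
        candidates.append(("-", revcomp(seq), quals[::-1]))
    best = None
    for strand, s, q in candidates:
        score = aligner.score(region.ref_seq, s)
        if best is None or score > best[0]:
            best = (score, strand, s, q)
    score, strand, oseq, oquals = best
    if score < scoring.min_score:
        return Alignment(rid, region.name, -1, [], (), mapped=False,
                         score=score, strand=strand, query=oseq, quals=oquals)
    aln = aligner.align(region.ref_seq, oseq)[0]
    ref_start, cigar, ops = _path_to_ops(aln, region.ref_seq, oseq)
    edit_ops = left_normalize(ops, region.ref_seq, floor=ref_start)
    return Alignment(rid, region.name, ref_start, cigar, edit_ops,
                     mapped=True, score=score, strand=strand,
                     query=oseq, quals=oquals)


def _as_read(read):
    if hasattr(read, "sequence"):
        return read.read_id, read.sequence.upper(), tuple(read.qualities)
    rid, seq, quals = read
    if isinstance(quals, str):
        quals = tuple(ord(c) - 33 for c in quals)
    return rid, seq.upper(), tuple(quals)


@dataclass
class IngestStats:
    """Accounting for :func:`load_alignments`."""

    total: int = 0
    used: int = 0
    skipped_secondary: int = 0
    skipped_unmapped: int = 0
    skipped_off_region: int = 0


def load_alignments(path, region: AmpliconRegion,
                    stats: Optional[IngestStats] = None) -> Iterator[Alignment]:
    """Stream alignments from an external SAM/BAM file.

    Records may be in amplicon coordinates (reference name equal to the
    region name) or genome coordinates (any other reference name, shifted
    by ``region.genome_offset``); secondary/supplementary and unmapped
    records are skipped, as are records not overlapping the amplicon.
    CIGAR strings are converted to canonical edit operations against the
    amplicon reference.
    """
    import pysam

    stats = stats if stats is not None else IngestStats()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            stats.total += 1
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.skipped_secondary += 1
                continue
            if rec.reference_name == region.name:
                start = rec.reference_start
            else:
                start = rec.reference_start - region.genome_offset
            if start < 0 or start >= len(region.ref_seq):
                stats.skipped_off_region += 1
                continue
            aln = _from_sam_record(rec, start, region)
            if aln is None:
                stats.skipped_off_region += 1
                continue
            stats.used += 1
            yield aln


def _from_sam_record(rec, start: int, region: AmpliconRegion) -> Optional[Alignment]:
    seq = (rec.query_sequence or "").upper()
    quals = tuple(rec.query_qualities) if rec.query_qualities is not None \
        else tuple([30] * len(seq))
    ref = region.ref_seq
    ops: list[Edit] = []
    cigar: list[tuple[str, int]] = []
    t, q = start, 0
    for op, n in rec.cigartuples or []:
        if op in (0, 7, 8):  # M / = / X: walk base by base against amplicon ref
            if t + n > len(ref):
                return None
            for k in range(n):
                if ref[t + k] != seq[q + k]:
                    ops.append(Edit(t + k, ref[t + k], seq[q + k]))
                    _push(cigar, "X", 1)
                else:
                    _push(cigar, "=", 1)
            t += n
            q += n
        elif op == 1:  # I
            ops.append(Edit(t, "", seq[q:q + n]))
            _push(cigar, "I", n)
            q += n
        elif op == 2:  # D
            if t + n > len(ref):
                return None
            ops.append(Edit(t, ref[t:t + n], ""))
            _push(cigar, "D", n)
            t += n
        elif op == 4:  # S
            _push(cigar, "S", n)
            q += n
        elif op == 3:  # N — treat as deletion-like skip; unusual in amplicons
            ops.append(Edit(t, ref[t:t + n], ""))
            _push(cigar, "D", n)
            t += n
        elif op == 5:  # H consumes nothing
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op} in record {rec.query_name}")
    edit_ops = left_normalize(ops, ref, floor=start)
    return Alignment(rec.query_name, region.name, start, cigar, edit_ops,
                     mapped=True, score=float(rec.mapping_quality),
                     strand="-" if rec.is_reverse else "+",
                     query=seq, quals=quals)


def _push(cigar, op, n):
    if cigar and cigar[-1][0] == op:
        cigar[-1] = (op, cigar[-1][1] + n)
    else:
        cigar.append((op, n))
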