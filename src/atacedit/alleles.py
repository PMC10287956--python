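"""Allele classification and per-replicate counting.

Each aligned read is assigned exactly one disposition: an allele call
(WT, a named HDR allele, or a single deletion DEL(start,len)) or an
exclusion reason (unmapped, not spanning the analysis region, carrying
an insertion, or an unclassifiable edit combination, OTHER).  Insertion
reads are excluded by default — unless the experiment's HDR allele is
itself an insertion, in which case reads matching that allele's edits
exactly are called HDR.

Deletion alleles additionally pass through :func:`filter_window`: only
deletions wholly contained within ``snp_pos ± window`` enter the
deletion effect analysis, because ATAC reads are short and variable in
length, so longer deletions are not captured reliably.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import Alignment
from .region import AmpliconRegion, Edit

logger = logging.getLogger(__name__)


class Kind(enum.IntEnum):
    """Allele categories, in canonical output order."""

    WT = 0
    HDR = 1
    DEL = 2
    INS = 3
    OTHER = 4


@dataclass(frozen=True, order=True)
class AlleleKey:
    """Canonical identity of a read's allele; totally ordered for
    deterministic output (WT < HDR < DEL by (start,len) < INS < OTHER)."""

    kind: Kind
    hdr_name: str = ""
    del_start: int = -1
    del_len: int = 0

    def __post_init__(self):
        if self.kind is Kind.DEL and self.del_len < 1:
            raise ValueError("DEL allele requires del_len >= 1")

    @property
    def label(self) -> str:
        if self.kind is Kind.HDR:
            return f"HDR:{self.hdr_name}"
        if self.kind is Kind.DEL:
            return f"DEL:{self.del_start}:{self.del_len}"
        return self.kind.name

    @classmethod
    def from_label(cls, label: str) -> "AlleleKey":
        parts = label.split(":")
        if parts[0] == "HDR":
            return cls(Kind.HDR, hdr_name=":".join(parts[1:]))
        if parts[0] == "DEL":
            return cls(Kind.DEL, del_start=int(parts[1]), del_len=int(parts[2]))
        return cls(Kind[parts[0]])

    def __str__(self) -> str:
        return self.label


WT = AlleleKey(Kind.WT)


@dataclass(frozen=True)
class Excluded:
    """Disposition of a read that does not enter the count table."""

    reason: str  # unmapped | short_span | insertion


@dataclass(frozen=True)
class Replicate:
    replicate_id: str
    readout: str  # ATAC | gDNA | RNA

    def __post_init__(self):
        if self.readout not in ("ATAC", "gDNA", "RNA"):
            raise ValueError(f"unknown readout {self.readout!r}")


def classify_read(aln: Alignment, region: AmpliconRegion):
    """Classify one alignment into an :class:`AlleleKey` or :class:`Excluded`.

    The call is decided by the edit operations overlapping the analysis
    span (``snp_pos ± window`` plus all HDR edit loci); reads that do not
    fully span it are excluded (``short_span``).  Substitutions outside
    the span never affect the call — at realistic per-base error rates
    most reads carry at least one off-span miscall, and treating those
    as real edits would misclassify them wholesale — while insertions
    and deletions anywhere on the read always count, since they are
    genuine repair outcomes wherever they fall.
    """
    if not aln.mapped:
        return Excluded("unmapped")
    lo, hi = region.analysis_span
    if aln.ref_start > lo or aln.ref_end - 1 < hi:
        return Excluded("short_span")

    ops = _denoise(aln, region)
    if not ops:
        return WT
    for spec in region.hdr_alleles:
        if ops == spec.edits:
            return AlleleKey(Kind.HDR, hdr_name=spec.name)
    if any(e.is_insertion for e in ops):
        return Excluded("insertion")
    if len(ops) == 1 and ops[0].is_deletion:
        d = ops[0]
        return AlleleKey(Kind.DEL, del_start=d.ref_offset, del_len=len(d.ref_bases))
    return AlleleKey(Kind.OTHER)


def _denoise(aln: Alignment, region: AmpliconRegion) -> tuple[Edit, ...]:
    """Restrict to call-relevant ops: indels anywhere, substitutions in span."""
    lo, hi = region.analysis_span
    return tuple(e for e in aln.edit_ops
                 if not e.is_substitution or e.overlaps(lo, hi))


def filter_window(key: AlleleKey, region: AmpliconRegion) -> bool:
    """True iff every deleted base lies within ``snp_pos ± window`` (inclusive)."""
    if key.kind is not Kind.DEL:
        raise ValueError("filter_window applies to DEL alleles only")
    lo = region.snp_pos - region.window
    hi = region.snp_pos + region.window
    return key.del_start >= lo and key.del_start + key.del_len - 1 <= hi


DROP_REASONS = ("unmapped", "short_span", "insertion")


@dataclass
class AlleleCountTable:
    """Replicate × allele read counts for one region.

    ``counts`` is a DataFrame indexed by replicate_id with
    :class:`AlleleKey` columns in canonical order; ``dropped`` tallies
    excluded reads per replicate by reason.
    """

    region: AmpliconRegion
    replicates: list[Replicate]
    counts: pd.DataFrame
    dropped: pd.DataFrame

    def __post_init__(self):
        if WT not in self.counts.columns:
            self.counts[WT] = 0
        self.counts = self.counts[sorted(self.counts.columns)].astype(int)

    @property
    def readouts(self) -> pd.Series:
        return pd.Series({r.replicate_id: r.readout for r in self.replicates},
                         name="readout")

    def replicate_ids(self, readout: str) -> list[str]:
        return [r.replicate_id for r in self.replicates if r.readout == readout]

    def alleles(self, kind: Optional[Kind] = None) -> list[AlleleKey]:
        keys = list(self.counts.columns)
        if kind is not None:
            keys = [k for k in keys if k.kind is kind]
        return keys

    def window_deletions(self) -> list[AlleleKey]:
        """Deletion alleles wholly contained in the analysis window."""
        return [k for k in self.alleles(Kind.DEL) if filter_window(k, self.region)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format TSV-ready view (region, replicate, readout, allele, count)."""
        rows = []
        readouts = self.readouts
        for rep_id, row in self.counts.iterrows():
            for key, count in row.items():
                rows.append((self.region.name, rep_id, readouts[rep_id],
                             key.label, int(count)))
        return pd.DataFrame(rows, columns=["region", "replicate", "readout",
                                           "allele", "count"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, region: AmpliconRegion) -> "AlleleCountTable":
        """Inverse of :meth:`to_frame` (used by the CLI stage hand-off)."""
        frame = frame[frame["region"] == region.name]
        reps = [Replicate(rid, ro) for (rid, ro), _ in
                frame.groupby(["replicate", "readout"], sort=False)]
        wide = frame.pivot_table(index="replicate", columns="allele",
                                 values="count", aggfunc="sum", fill_value=0)
        wide.columns = [AlleleKey.from_label(c) for c in wide.columns]
        wide = wide.reindex([r.replicate_id for r in reps])
        dropped = pd.DataFrame(0, index=wide.index, columns=list(DROP_REASONS))
        return cls(region, reps, wide, dropped)


def count_alleles(alignments: Iterable[tuple[str, Alignment]],
                  region: AmpliconRegion,
                  replicate_layout: Sequence[Replicate]) -> AlleleCountTable:
    """Tabulate allele calls per replicate.

    ``alignments`` yields ``(replicate_id, Alignment)`` pairs; every
    replicate in ``replicate_layout`` gets a row even if it received no
    reads (flagged with a warning, and excluded from statistics
    downstream).
    """
    rep_ids = [r.replicate_id for r in replicate_layout]
    if len(set(rep_ids)) != len(rep_ids):
        raise ValueError("duplicate replicate ids in layout")
    counts: dict[str, dict[AlleleKey, int]] = {r: {} for r in rep_ids}
    dropped = {r: dict.fromkeys(DROP_REASONS, 0) for r in rep_ids}
    for rep_id, aln in alignments:
        if rep_id not in counts:
            raise KeyError(f"read {aln.read_id!r} assigned to unknown replicate {rep_id!r}")
        call = classify_read(aln, region)
        if isinstance(call, Excluded):
            dropped[rep_id][call.reason] += 1
        else:
            counts[rep_id][call] = counts[rep_id].get(call, 0) + 1

    all_keys = sorted({k for per_rep in counts.values() for k in per_rep} | {WT})
    mat = pd.DataFrame(
        [[counts[r].get(k, 0) for k in all_keys] for r in rep_ids],
        index=pd.Index(rep_ids, name="replicate"), columns=all_keys)
    drop = pd.DataFrame([[dropped[r][reason] for reason in DROP_REASONS]
                         for r in rep_ids],
                        index=mat.index, columns=list(DROP_REASONS))
    table = AlleleCountTable(region, list(replicate_layout), mat, drop)
    for r in rep_ids:
        if mat.loc[r].sum() == 0:
            warnings.warn(f"replicate {r!r} has zero classified reads; "
                          "it will be excluded from statistics", stacklevel=2)
    return table


def top_deletions(table: AlleleCountTable, k: int = 2) -> list[AlleleKey]:
    """The ``k`` most prevalent window-contained deletions.

    Prevalence is the total gDNA read count (gDNA reflects allele
    frequency in the pool; the ATAC readout would bias selection toward
    accessible alleles).  Ties break toward smaller start, then smaller
    length.
    """
    if k <= 0:
        return []
    gdna = table.replicate_ids("gDNA")
    dels = table.window_deletions()
    totals = {d: int(table.counts.loc[gdna, d].sum()) for d in dels}
    ranked = sorted(dels, key=lambda d: (-totals[d], d.del_start, d.del_len))
    return ranked[:k]


def write_counts(table: AlleleCountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_qc(table: AlleleCountTable, path) -> None:
    """Per-replicate QC TSV: classified totals and drop-reason tallies."""
    qc = table.dropped.copy()
    qc.insert(0, "classified", table.counts.sum(axis=1))
    qc.insert(0, "readout", table.readouts)
    qc.insert(0, "region", table.region.name)
    qc.to_csv(path, sep="\t")
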