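"""Amplicon region definitions.

An :class:`AmpliconRegion` anchors all coordinates used downstream: the
amplicon reference sequence (primer to primer), the targeted SNP/edit
offset, the Cas9 cut site, the deletion-analysis window and the precise
HDR (homology-directed repair) allele definitions.  Offsets are 0-based
into ``ref_seq``; ``genome_offset`` records where the amplicon starts in
genome coordinates and is metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import yaml

_IUPAC = set("ACGTRYSWKMBDHVN")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                           "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Edit:
    """One primitive edit against the amplicon reference.

    Substitution when ``len(ref_bases) == len(alt_bases)``, insertion when
    ``ref_bases`` is empty, deletion when ``alt_bases`` is empty.
    ``ref_offset`` is the 0-based offset of the first reference base
    affected (for an insertion: the base before which ``alt_bases`` are
    inserted).
    """

    ref_offset: int
    ref_bases: str
    alt_bases: str

    @property
    def is_substitution(self) -> bool:
        return len(self.ref_bases) == len(self.alt_bases) and self.ref_bases != ""

    @property
    def is_insertion(self) -> bool:
        return self.ref_bases == "" and self.alt_bases != ""

    @property
    def is_deletion(self) -> bool:
        return self.alt_bases == "" and self.ref_bases != ""

    @property
    def ref_end(self) -> int:
        """One past the last reference offset consumed."""
        return self.ref_offset + len(self.ref_bases)

    def overlaps(self, start: int, end: int) -> bool:
        """True if the edit touches reference interval [start, end] (inclusive).

        Insertions are zero-width on the reference; they overlap when the
        insertion point lies within (start, end] boundaries.
        """
        if self.is_insertion:
            return start <= self.ref_offset <= end + 1
        return self.ref_offset <= end and self.ref_end - 1 >= start


@dataclass(frozen=True)
class HdrAlleleSpec:
    """A named HDR allele, defined by one or more non-overlapping edits."""

    name: str
    edits: tuple[Edit, ...]

    def __post_init__(self):
        if not self.edits:
            raise ValueError(f"HDR allele {self.name!r} has no edits")
        edits = tuple(sorted(self.edits))
        object.__setattr__(self, "edits", edits)
        for a, b in zip(edits, edits[1:]):
            if b.ref_offset < a.ref_end:
                raise ValueError(f"HDR allele {self.name!r} has overlapping edits")

    @property
    def has_insertion(self) -> bool:
        return any(e.is_insertion for e in self.edits)


@dataclass
class AmpliconRegion:
    """The targeted amplicon and everything needed to interpret reads on it.

    Parameters
    ----------
    name
        Region identifier (used in outputs and SAM record matching).
    ref_seq
        Amplicon reference sequence, primer to primer, uppercase ACGT.
    snp_pos
        0-based offset of the targeted SNP/edit site in ``ref_seq``.
    cut_site
        0-based offset of the base 5' of the blunt Cas9 cut.
    window
        Half-width (bp) of the deletion-analysis window around ``snp_pos``;
        deletions must be wholly contained in ``snp_pos ± window`` to enter
        the deletion analysis.  Default 6.
    hdr_alleles
        HDR allele definitions for this region.
    genome_offset
        Genome coordinate (0-based) of ``ref_seq[0]``; metadata used only to
        translate externally aligned records into amplicon offsets.
    primer_fixed_end
        Which amplicon end carries the fixed nested primer in ATAC reads
        ("left" or "right"); ATAC reads run from this end to a variable Tn5
        insertion site.
    """

    name: str
    ref_seq: str
    snp_pos: int
    cut_site: int
    window: int = 6
    hdr_alleles: list[HdrAlleleSpec] = field(default_factory=list)
    genome_offset: int = 0
    primer_fixed_end: str = "left"

    def __post_init__(self):
        self.ref_seq = self.ref_seq.upper()
        bad = set(self.ref_seq) - _IUPAC
        if bad:
            raise ValueError(f"region {self.name!r}: non-IUPAC bases {sorted(bad)}")
        n = len(self.ref_seq)
        if not (0 <= self.snp_pos < n):
            raise ValueError(f"region {self.name!r}: snp_pos {self.snp_pos} outside [0,{n})")
        if not (0 <= self.cut_site < n):
            raise ValueError(f"region {self.name!r}: cut_site {self.cut_site} outside [0,{n})")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.primer_fixed_end not in ("left", "right"):
            raise ValueError("primer_fixed_end must be 'left' or 'right'")
        if n >= 295:
            warnings.warn(
                f"region {self.name!r}: amplicon is {n} bp; amplicons are expected "
                "to be <295 bp so that 2x150 bp reads overlap", stacklevel=2)
        names = [h.name for h in self.hdr_alleles]
        if len(names) != len(set(names)):
            raise ValueError(f"region {self.name!r}: duplicate HDR allele names")

    @property
    def analysis_span(self) -> tuple[int, int]:
        """Inclusive reference interval a read must cover to be classified.

        Union of the deletion window ``snp_pos ± window`` (clipped to the
        amplicon) and every HDR edit locus.
        """
        lo = max(0, self.snp_pos - self.window)
        hi = min(len(self.ref_seq) - 1, self.snp_pos + self.window)
        for spec in self.hdr_alleles:
            for e in spec.edits:
                lo = min(lo, max(0, e.ref_offset - (1 if e.is_insertion else 0)))
                hi = max(hi, min(len(self.ref_seq) - 1,
                                 max(e.ref_offset, e.ref_end - 1)))
        return lo, hi

    def hdr_spec(self, name: str) -> HdrAlleleSpec:
        for spec in self.hdr_alleles:
            if spec.name == name:
                return spec
        raise KeyError(name)


def apply_edits(ref_seq: str, edits: Iterable[Edit]) -> str:
    """Apply sorted, non-overlapping edits to a reference sequence."""
    out = []
    pos = 0
    for e in sorted(edits):
        if e.ref_offset < pos:
            raise ValueError("edits overlap or are unsorted")
        if e.ref_bases and ref_seq[e.ref_offset:e.ref_end] != e.ref_bases:
            raise ValueError(
                f"edit at {e.ref_offset} expects {e.ref_bases!r}, reference has "
                f"{ref_seq[e.ref_offset:e.ref_end]!r}")
        out.append(ref_seq[pos:e.ref_offset])
        out.append(e.alt_bases)
        pos = e.ref_end
    out.append(ref_seq[pos:])
    return "".join(out)


def _edit_from_dict(d: dict) -> Edit:
    return Edit(int(d["ref_offset"]), str(d.get("ref", d.get("ref_bases", ""))).upper(),
                str(d.get("alt", d.get("alt_bases", ""))).upper())


def region_from_dict(d: dict) -> AmpliconRegion:
    """Build an :class:`AmpliconRegion` from a config mapping (YAML-friendly)."""
    hdr = [HdrAlleleSpec(h["name"], tuple(_edit_from_dict(e) for e in h["edits"]))
           for h in d.get("hdr_alleles", [])]
    return AmpliconRegion(
        name=str(d["name"]),
        ref_seq=str(d["ref_seq"]),
        snp_pos=int(d["snp_pos"]),
        cut_site=int(d["cut_site"]),
        window=int(d.get("window", 6)),
        hdr_alleles=hdr,
        genome_offset=int(d.get("genome_offset", 0)),
        primer_fixed_end=str(d.get("primer_fixed_end", "left")),
    )


def load_regions(path) -> list[AmpliconRegion]:
    """Load regions from a YAML file with a top-level ``regions`` list."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    items = doc["regions"] if isinstance(doc, dict) and "regions" in doc else doc
    return [region_from_dict(d) for d in items]
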