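"""Synthetic edited-pool read simulator with known ground truth.

The generative model mirrors the assay's structure.  A pool of cells
carries a mixture of alleles (WT, HDR point edits or insertions, and a
repertoire of Cas9 deletions around the cut site) at fixed frequencies.
gDNA amplicon reads sample alleles at those frequencies and span the
full amplicon.  ATAC reads sample alleles at frequencies *tilted* by a
per-allele accessibility multiplier (an allele twice as accessible is
tagmented — hence sequenced — twice as often), and each read runs from
the fixed nested-primer end of the amplicon to a variable Tn5 insertion
site drawn from an accessibility profile over the amplicon.  Sequencing
error is i.i.d. per base.

The accessibility multiplier acts on allele sampling probability, not on
fragment length: the assay measures relative read abundance, so this is
the minimal generative model consistent with the readout.  The
multiplier for an allele is therefore exactly the effect size the
downstream statistics should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alleles import (AlleleCountTable, AlleleKey, Kind, Replicate, WT,
                      DROP_REASONS)
from .region import AmpliconRegion, Edit, apply_edits

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults reflect a typical targeted-ATAC experiment: three ATAC and
    three gDNA replicates, 10^4 reads per replicate, 150-bp reads and a
    0.1% per-base error rate (Illumina-like).  ``atac_profile`` gives the
    Tn5 insertion propensity per reference offset; ``None`` uses a
    triangular peak centred mid-amplicon (most reads short near the peak
    flanks).
    """

    region: AmpliconRegion
    allele_freqs: dict[AlleleKey, float]
    accessibility: dict[AlleleKey, float] = field(default_factory=dict)
    atac_profile: Optional[np.ndarray] = None
    read_len: int = 150
    per_base_error: float = 0.001
    n_atac_reps: int = 3
    n_gdna_reps: int = 3
    reads_per_rep: int = 10_000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.allele_freqs.values()):
            raise ValueError("allele frequencies must be non-negative")
        self.accessibility = {WT: 1.0, **self.accessibility}
        if self.accessibility[WT] != 1.0:
            raise ValueError("accessibility of WT must be 1")
        for k in self.allele_freqs:
            self.accessibility.setdefault(k, 1.0)
            if self.accessibility[k] <= 0:
                raise ValueError(f"accessibility of {k.label} must be > 0")
        if self.atac_profile is None:
            self.atac_profile = triangular_profile(len(self.region.ref_seq))
        self.atac_profile = np.asarray(self.atac_profile, dtype=float)
        if (self.atac_profile < 0).any() or self.atac_profile.sum() == 0:
            raise ValueError("atac_profile weights must be non-negative, not all zero")
        if len(self.atac_profile) != len(self.region.ref_seq):
            raise ValueError("atac_profile length must match the amplicon")
        if not (0 <= self.per_base_error < 1):
            raise ValueError("per_base_error must be in [0, 1)")

    @property
    def alleles(self) -> list[AlleleKey]:
        return sorted(self.allele_freqs)


@dataclass
class GroundTruth:
    """Closed-form expectations plus the realized per-replicate draws."""

    effect_sizes: dict[AlleleKey, float]
    hdr_rate: float
    indel_rate: float
    sampled_counts: Optional[pd.DataFrame] = None

    def to_json(self, path) -> None:
        doc = {
            "effect_sizes": {k.label: v for k, v in self.effect_sizes.items()},
            "hdr_rate": self.hdr_rate,
            "indel_rate": self.indel_rate,
        }
        if self.sampled_counts is not None:
            doc["sampled_counts"] = {
                rep: {k.label: int(c) for k, c in row.items()}
                for rep, row in self.sampled_counts.iterrows()}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def triangular_profile(n: int) -> np.ndarray:
    """Triangular Tn5 insertion propensity peaking mid-amplicon."""
    x = np.arange(n, dtype=float)
    return 1.0 + np.minimum(x, n - 1 - x)


def default_indel_spectrum(region: AmpliconRegion, n_deletions: int,
                           rng: np.random.Generator,
                           total_mass: float = 1.0) -> dict[AlleleKey, float]:
    """Random repertoire of deletion alleles around the cut site.

    Lengths are geometric with mean 4 bp; starts are placed so the
    deletion straddles or abuts the blunt cut (between ``cut_site`` and
    ``cut_site + 1``); frequencies are Dirichlet-distributed over the
    allocated ``total_mass``.  Deterministic for a given generator state.
    """
    if n_deletions < 1:
        raise ValueError("n_deletions must be >= 1")
    ref_len = len(region.ref_seq)
    keys: list[AlleleKey] = []
    seen = set()
    while len(keys) < n_deletions:
        length = int(rng.geometric(1 / 4.0))
        length = min(length, ref_len - 2)
        start = int(rng.integers(region.cut_site - length + 1,
                                 region.cut_site + 2))
        start = int(np.clip(start, 0, ref_len - length))
        key = AlleleKey(Kind.DEL, del_start=start, del_len=length)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    weights = rng.dirichlet(np.ones(n_deletions))
    return {k: float(w * total_mass) for k, w in zip(keys, weights)}


def allele_sequence(region: AmpliconRegion, key: AlleleKey) -> str:
    """Full amplicon sequence carried by an allele."""
    if key.kind is Kind.WT:
        return region.ref_seq
    if key.kind is Kind.HDR:
        return apply_edits(region.ref_seq, region.hdr_spec(key.hdr_name).edits)
    if key.kind is Kind.DEL:
        e = Edit(key.del_start,
                 region.ref_seq[key.del_start:key.del_start + key.del_len], "")
        return apply_edits(region.ref_seq, [e])
    raise ValueError(f"cannot generate a sequence for allele kind {key.kind.name}")


def _replicate_layout(cfg: SimConfig) -> list[Replicate]:
    return ([Replicate(f"ATAC{i + 1}", "ATAC") for i in range(cfg.n_atac_reps)]
            + [Replicate(f"gDNA{i + 1}", "gDNA") for i in range(cfg.n_gdna_reps)])


def simulate_counts(cfg: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> AlleleCountTable:
    """Draw per-replicate allele counts (the count-level generative core).

    gDNA replicates are multinomial draws at the pool frequencies; ATAC
    replicates are multinomial draws at frequencies tilted by the
    accessibility multipliers.  Read synthesis (:func:`simulate_pool`)
    assigns sequences to exactly these draws, so at zero sequencing error
    the two paths produce identical count tables.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    alleles = cfg.alleles
    f = np.array([cfg.allele_freqs[a] for a in alleles], dtype=float)
    m = np.array([cfg.accessibility[a] for a in alleles], dtype=float)
    p_atac = f * m
    p_atac /= p_atac.sum()
    layout = _replicate_layout(cfg)
    rows = []
    for rep in layout:
        p = p_atac if rep.readout == "ATAC" else f / f.sum()
        rows.append(rng.multinomial(cfg.reads_per_rep, p))
    counts = pd.DataFrame(rows, index=pd.Index([r.replicate_id for r in layout],
                                               name="replicate"),
                          columns=alleles)
    dropped = pd.DataFrame(0, index=counts.index, columns=list(DROP_REASONS))
    return AlleleCountTable(cfg.region, layout, counts, dropped)


def expected_truth(cfg: SimConfig,
                   sampled: Optional[AlleleCountTable] = None) -> GroundTruth:
    """Closed-form expectations implied by a configuration."""
    effects = {a: cfg.accessibility[a] for a in cfg.alleles}
    hdr = sum(f for a, f in cfg.allele_freqs.items() if a.kind is Kind.HDR)
    indel = sum(f for a, f in cfg.allele_freqs.items()
                if a.kind in (Kind.DEL, Kind.INS, Kind.OTHER))
    return GroundTruth(effects, hdr, indel,
                       sampled_counts=None if sampled is None else sampled.counts)


def _ref_to_allele_pos(region: AmpliconRegion, key: AlleleKey) -> np.ndarray:
    """Map each reference offset (plus one-past-end) to allele coordinates."""
    n = len(region.ref_seq)
    edits: tuple[Edit, ...] = ()
    if key.kind is Kind.HDR:
        edits = region.hdr_spec(key.hdr_name).edits
    elif key.kind is Kind.DEL:
        edits = (Edit(key.del_start,
                      region.ref_seq[key.del_start:key.del_start + key.del_len],
                      ""),)
    pos = np.arange(n + 1)
    shift = np.zeros(n + 1, dtype=int)
    for e in edits:
        delta = len(e.alt_bases) - len(e.ref_bases)
        if e.is_deletion:
            # positions inside the deleted interval collapse to its start
            inside = (pos > e.ref_offset) & (pos < e.ref_end)
            shift[inside] = e.ref_offset - pos[inside]
            shift[pos >= e.ref_end] += delta
        else:
            shift[pos >= e.ref_end] += delta
    return pos + shift


def _atac_cut_positions(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Eligible Tn5 insertion offsets (reference coords) and their weights.

    The insertion site must lie beyond the analysis span as seen from the
    fixed primer end, so every ATAC read covers the span and is
    classifiable.
    """
    lo, hi = cfg.region.analysis_span
    n = len(cfg.region.ref_seq)
    if cfg.region.primer_fixed_end == "left":
        positions = np.arange(hi + 1, n + 1)  # read covers ref[0:pos]
        weights = cfg.atac_profile[hi:n]      # propensity at the last covered base
    else:
        positions = np.arange(0, lo + 1)      # read covers ref[pos:]
        weights = cfg.atac_profile[0:lo + 1]
    if len(positions) == 0 or weights.sum() == 0:
        raise ValueError("atac_profile has no mass beyond the analysis span; "
                         "no informative ATAC read can be generated")
    return positions, weights / weights.sum()


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        repl = _BASES[rng.integers(0, 4, size=len(idx))]
        same = repl == arr[idx]
        while same.any():
            repl[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = repl == arr[idx]
        arr[idx] = repl
    return arr.tobytes().decode()


def simulate_pool(cfg: SimConfig, out_dir,
                  paired: bool = False) -> tuple[dict[str, Path], GroundTruth]:
    """Write per-replicate FASTQ files and return the ground truth.

    Reads are emitted pre-merged (single-end) by default; ``paired=True``
    instead fragments each read into an overlapping R1/R2 pair (files
    ``<rep>_R1.fastq`` / ``<rep>_R2.fastq``) to exercise the merge stage.
    Fully deterministic for a given ``cfg.seed``.
    """
    from .region import revcomp

    cut_pos, cut_w = _atac_cut_positions(cfg)  # validate before touching disk
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    table = simulate_counts(cfg, rng)
    pos_maps = {a: _ref_to_allele_pos(cfg.region, a) for a in cfg.alleles}
    seqs = {a: allele_sequence(cfg.region, a) for a in cfg.alleles}
    qchar = chr(33 + _phred(cfg.per_base_error))

    paths: dict[str, Path] = {}
    for rep in table.replicates:
        reads: list[tuple[str, str]] = []
        for allele in cfg.alleles:
            count = int(table.counts.loc[rep.replicate_id, allele])
            full = seqs[allele]
            if rep.readout == "ATAC":
                cuts = cut_pos[rng.choice(len(cut_pos), size=count, p=cut_w)]
            else:
                cuts = None
            for i in range(count):
                if cuts is None:
                    frag = full
                else:
                    apos = int(pos_maps[allele][cuts[i]])
                    frag = (full[:apos] if cfg.region.primer_fixed_end == "left"
                            else full[apos:])
                frag = _add_errors(frag, cfg.per_base_error, rng)
                reads.append((f"{rep.replicate_id}:{allele.label}:{i}", frag))
        order = rng.permutation(len(reads))
        if paired:
            p1 = out_dir / f"{rep.replicate_id}_R1.fastq"
            p2 = out_dir / f"{rep.replicate_id}_R2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for j in order:
                    rid, seq = reads[j]
                    r1 = seq[:cfg.read_len]
                    r2 = revcomp(seq[-cfg.read_len:])
                    f1.write(f"@{rid}\n{r1}\n+\n{qchar * len(r1)}\n")
                    f2.write(f"@{rid}\n{r2}\n+\n{qchar * len(r2)}\n")
            paths[rep.replicate_id] = p1
            paths[rep.replicate_id + "/R2"] = p2
        else:
            p = out_dir / f"{rep.replicate_id}.fastq"
            with open(p, "w") as fh:
                for j in order:
                    rid, seq = reads[j]
                    fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")
            paths[rep.replicate_id] = p
    truth = expected_truth(cfg, sampled=table)
    return paths, truth


def _phred(error: float) -> int:
    if error <= 0:
        return 40
    return int(min(40, max(2, round(-10 * np.log10(error)))))
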