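"""Saturation-mutagenesis effect profiles over a binding site.

A multiplexed experiment introduces every possible single-base
substitution across a transcription-factor binding site; the per-allele
effect sizes are arranged into a position × nucleotide matrix
(:class:`MotifEffectProfile`) and summarized three ways:

* a sequence-logo height matrix, letter size proportional to the
  *square* of the effect size relative to WT (set to 1);
* per-position proportions (effect divided by the sum over the four
  nucleotides), comparable to a position frequency matrix; and
* an importance score, the inverse of the effect size — a base whose
  mutation collapses accessibility is an important base.

Profiles can be correlated cell-by-cell against a JASPAR-format PFM.
Bases that could not be mutated (e.g. the N of the NGG PAM, where any
edit invites Cas9 re-cutting) are carried as masked cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .region import AmpliconRegion
from .stats import EffectResult

BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MotifEffectProfile:
    """position × nucleotide matrix of effect sizes.

    ``effect``/``ci_low``/``ci_high`` are DataFrames indexed by reference
    offset with columns A,C,G,T; ``mask`` is True where a cell was not
    measured (missing allele or PAM-constrained).  The WT base at each
    position has effect 1 by definition.
    """

    positions: list[int]
    wt_base: dict[int, str]
    effect: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        for pos in self.positions:
            assert self.effect.loc[pos, self.wt_base[pos]] == 1.0


def build_profile(results: dict[tuple[int, str], EffectResult],
                  region: AmpliconRegion,
                  masked: Optional[set[tuple[int, str]]] = None) -> MotifEffectProfile:
    """Arrange per-substitution effect results into a profile.

    ``results`` maps ``(reference offset, alternate base)`` to the
    allele's :class:`~atacedit.stats.EffectResult`; each pair may appear
    at most once and the WT base itself is the reference (supplying a
    result for it is an error).  Missing cells and any ``masked`` cells
    are flagged in the mask.
    """
    masked = masked or set()
    positions = sorted({p for p, _ in results} | {p for p, _ in masked})
    wt = {p: region.ref_seq[p] for p in positions}
    effect = pd.DataFrame(np.nan, index=positions, columns=list(BASES))
    lo = effect.copy()
    hi = effect.copy()
    mask = pd.DataFrame(True, index=positions, columns=list(BASES))
    for (pos, base), res in results.items():
        base = base.upper()
        if base == wt[pos]:
            raise ValueError(
                f"result supplied for the WT base {base} at {pos}; "
                "WT is the reference, not a substitution")
        if not mask.loc[pos, base]:
            raise ValueError(f"duplicate result for ({pos}, {base})")
        effect.loc[pos, base] = res.effect_size
        lo.loc[pos, base] = res.ci_low
        hi.loc[pos, base] = res.ci_high
        mask.loc[pos, base] = False
    for p in positions:
        effect.loc[p, wt[p]] = 1.0
        lo.loc[p, wt[p]] = 1.0
        hi.loc[p, wt[p]] = 1.0
        mask.loc[p, wt[p]] = False
    return MotifEffectProfile(positions, wt, effect, lo, hi, mask)


def logo_heights(profile: MotifEffectProfile) -> pd.DataFrame:
    """Letter heights: the squared effect size; WT cell 1; masked cells 0."""
    h = profile.effect.pow(2)
    h = h.where(~profile.mask, 0.0)
    return h.fillna(0.0)


def importance_scores(profile: MotifEffectProfile) -> pd.DataFrame:
    """Inverse effect size — how much the base matters for accessibility."""
    imp = 1.0 / profile.effect
    return imp.where(~profile.mask, np.nan)


def motif_proportions(profile: MotifEffectProfile) -> pd.DataFrame:
    """Per-position effect proportions (rows sum to 1).

    Positions with any masked cell are excluded: the proportion is only
    meaningful when all four nucleotides were measured.
    """
    complete = [p for p in profile.positions if not profile.mask.loc[p].any()]
    eff = profile.effect.loc[complete]
    return eff.div(eff.sum(axis=1), axis=0)


def proportion_cis(profile: MotifEffectProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CI bounds on the proportion scale.

    Each bound is divided by the per-position sum of the point estimates
    (the sum's own uncertainty is not propagated).
    """
    complete = [p for p in profile.positions if not profile.mask.loc[p].any()]
    denom = profile.effect.loc[complete].sum(axis=1)
    return (profile.ci_low.loc[complete].div(denom, axis=0),
            profile.ci_high.loc[complete].div(denom, axis=0))


@dataclass
class PositionFrequencyMatrix:
    """A motif PFM: per-position base counts (or probabilities)."""

    name: str
    counts: pd.DataFrame  # index 0..L-1, columns A,C,G,T

    def __post_init__(self):
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("PFM has an all-zero position")
        if (self.counts < 0).to_numpy().any():
            raise ValueError("PFM counts must be non-negative")

    @property
    def length(self) -> int:
        return len(self.counts)

    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def reverse_complement(self) -> "PositionFrequencyMatrix":
        rc = self.counts.iloc[::-1].reset_index(drop=True)
        rc.columns = [_COMP[b] for b in self.counts.columns]
        return PositionFrequencyMatrix(self.name, rc[list(BASES)])


def read_pfm(path_or_handle) -> PositionFrequencyMatrix:
    """Read a JASPAR-format PFM (">header + matrix" or raw 4-line dialect)."""
    from Bio import motifs

    if hasattr(path_or_handle, "read"):
        text = path_or_handle.read()
        name = "PFM"
    else:
        text = open(path_or_handle).read()
        name = str(path_or_handle)
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    m = motifs.read(io.StringIO(text), fmt)
    counts = pd.DataFrame({b: list(m.counts[b]) for b in BASES})
    return PositionFrequencyMatrix(m.name or name, counts)


def compare_to_pfm(props: pd.DataFrame, pfm: PositionFrequencyMatrix,
                   offset: int, strand: str = "+"
                   ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between effect proportions and a PFM.

    ``offset`` maps profile reference offsets to PFM columns: profile
    position ``p`` pairs with PFM column ``p - offset`` (forward strand)
    or its reverse complement (``strand='-'``).  The mapping is explicit
    configuration, never inferred.  Returns ``(pearson_r, per-cell
    table)``; r is NaN (flagged degenerate) if either vector is
    constant.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    target = pfm.proportions() if strand == "+" \
        else pfm.reverse_complement().proportions()
    rows = []
    for p in props.index:
        j = p - offset
        if not (0 <= j < pfm.length):
            continue
        for b in BASES:
            rows.append((p, b, float(props.loc[p, b]), float(target.loc[j, b])))
    if len({r[0] for r in rows}) < 2:
        raise ValueError("fewer than 2 profile positions overlap the PFM")
    table = pd.DataFrame(rows, columns=["position", "base",
                                        "profile_prop", "pfm_prop"])
    x, y = table["profile_prop"].to_numpy(), table["pfm_prop"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), table
    r = float(sps.pearsonr(x, y).statistic)
    return r, table


def render_text_logo(heights: pd.DataFrame, rows: int = 10) -> str:
    """Plain-text logo: per position, a column of letters scaled to height."""
    lines = []
    hmax = float(heights.to_numpy().max()) or 1.0
    grid = {}
    for pos in heights.index:
        order = heights.loc[pos].sort_values(ascending=False)
        col = []
        for base, h in order.items():
            col.extend([base] * int(round(rows * h / hmax)))
        grid[pos] = col[:rows]
    for level in range(rows - 1, -1, -1):
        lines.append(" ".join(
            (grid[pos][level] if level < len(grid[pos]) else ".")
            for pos in heights.index))
    lines.append("-" * (2 * len(heights.index) - 1))
    lines.append(" ".join(str(pos % 10) for pos in heights.index))
    return "\n".join(lines)
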