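"""Effect-size statistics for edited-pool accessibility assays.

For each allele X and each replicate, the primary quantity is the ratio
of X's read count to the wild-type count, ``r = count(X)/count(WT)``.
The mean of this ratio over ATAC replicates (r_A) and over gDNA
replicates (r_G) are compared: if X alters chromatin accessibility the
two differ, and the effect size ``r_A / r_G`` measures the fold change
in accessibility (1 = no effect).  Significance comes from a two-tailed
unequal-variance (Welch) t-test on the per-replicate ratios.

Confidence intervals are built on the log-ratio scale (Welch CI of the
difference of mean log ratios, exponentiated) so that they stay positive
and symmetric on the natural ratio scale; a replicate where the allele
has zero reads contributes r = 0 to the means, and for the log-scale CI
only, a pseudocount of 0.5 reads replaces the zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alleles import AlleleCountTable, AlleleKey, Kind, WT, top_deletions

_PSEUDOCOUNT = 0.5


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom.  Degenerate inputs follow a fixed convention: both samples
    constant with equal means → ``(0, nx+ny-2, 1)``; both constant with
    unequal means → ``(±inf, nx+ny-2, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least two observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        warnings.warn("both samples have zero variance and unequal means; "
                      "p-value degenerates to 0", stacklevel=2)
        return math.copysign(float("inf"), x.mean() - y.mean()), df, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2 ** 2 / (vx ** 2 / (len(x) ** 2 * (len(x) - 1))
                     + vy ** 2 / (len(y) ** 2 * (len(y) - 1)))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class EffectResult:
    """Per-allele accessibility effect relative to wild type."""

    allele: AlleleKey
    r_atac_mean: float
    r_gdna_mean: float
    effect_size: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p_value: float
    n_atac: int
    n_gdna: int
    ratios_atac: tuple[float, ...] = ()
    ratios_gdna: tuple[float, ...] = ()
    label: str = ""  # overrides allele.label for pooled pseudo-alleles

    @property
    def name(self) -> str:
        return self.label or self.allele.label


def _usable_replicates(table: AlleleCountTable, readout: str) -> list[str]:
    """Replicates of a readout with WT reads (ratio denominators)."""
    reps = table.replicate_ids(readout)
    usable = []
    for r in reps:
        if table.counts.loc[r, WT] > 0:
            usable.append(r)
        else:
            warnings.warn(f"replicate {r!r} has zero WT reads; excluded from "
                          "ratio statistics", stacklevel=3)
    return usable


def _effect_from_counts(allele_counts: pd.Series, table: AlleleCountTable,
                        allele: AlleleKey, label: str = "") -> EffectResult:
    atac = _usable_replicates(table, "ATAC")
    gdna = _usable_replicates(table, "gDNA")
    if not atac or not gdna:
        raise ValueError("no usable replicate with WT reads in one of the readouts")
    wt = table.counts[WT]
    r_atac = (allele_counts[atac] / wt[atac]).to_numpy(dtype=float)
    r_gdna = (allele_counts[gdna] / wt[gdna]).to_numpy(dtype=float)
    ra, rg = r_atac.mean(), r_gdna.mean()
    effect = ra / rg if rg > 0 else float("nan")

    if len(r_atac) >= 2 and len(r_gdna) >= 2:
        t, df, p = welch_t(r_atac, r_gdna)
    else:
        t = df = p = float("nan")
    ci_low, ci_high = _log_ratio_ci(allele_counts, wt, atac, gdna)
    return EffectResult(allele, float(ra), float(rg), float(effect),
                        ci_low, ci_high, t, df, p,
                        n_atac=len(atac), n_gdna=len(gdna),
                        ratios_atac=tuple(r_atac), ratios_gdna=tuple(r_gdna),
                        label=label)


def _log_ratio_ci(allele_counts: pd.Series, wt: pd.Series,
                  atac: list[str], gdna: list[str],
                  level: float = 0.95) -> tuple[float, float]:
    """95% CI of the effect size via Welch CI of mean log-ratio difference.

    Zeros in the allele counts are replaced by a 0.5-read pseudocount
    here only, so the log is defined; the point estimates are untouched.
    """
    def logr(reps):
        c = allele_counts[reps].to_numpy(dtype=float)
        c = np.where(c > 0, c, _PSEUDOCOUNT)
        return np.log(c / wt[reps].to_numpy(dtype=float))

    la, lg = logr(atac), logr(gdna)
    if len(la) < 2 or len(lg) < 2:
        return float("nan"), float("nan")
    d = la.mean() - lg.mean()
    va, vg = la.var(ddof=1), lg.var(ddof=1)
    se2 = va / len(la) + vg / len(lg)
    if se2 == 0.0:
        return float(np.exp(d)), float(np.exp(d))
    df = se2 ** 2 / (va ** 2 / (len(la) ** 2 * (len(la) - 1))
                     + vg ** 2 / (len(lg) ** 2 * (len(lg) - 1)))
    tcrit = sps.t.ppf(0.5 + level / 2, df)
    half = tcrit * math.sqrt(se2)
    return float(np.exp(d - half)), float(np.exp(d + half))


def effect_size(table: AlleleCountTable, allele: AlleleKey) -> EffectResult:
    """Effect of ``allele`` on accessibility relative to WT.

    WT itself is the normalization anchor: its effect size is 1 by
    construction and its p-value undefined (NaN).
    """
    if allele == WT:
        atac = _usable_replicates(table, "ATAC")
        gdna = _usable_replicates(table, "gDNA")
        nan = float("nan")
        return EffectResult(WT, 1.0, 1.0, 1.0, 1.0, 1.0, nan, nan, nan,
                            n_atac=len(atac), n_gdna=len(gdna),
                            ratios_atac=(1.0,) * len(atac),
                            ratios_gdna=(1.0,) * len(gdna))
    if allele not in table.counts.columns:
        raise KeyError(f"allele {allele.label} not present in count table")
    return _effect_from_counts(table.counts[allele], table, allele)


def deletion_window_effect(table: AlleleCountTable) -> Optional[EffectResult]:
    """Pooled effect of all deletions wholly inside the analysis window.

    Window-retained deletions are summed per replicate into one
    pseudo-allele before the standard effect computation; returns
    ``None`` (with a warning) when no deletion survives the window
    filter.
    """
    dels = table.window_deletions()
    if not dels:
        warnings.warn("no deletions wholly contained in the analysis window",
                      stacklevel=2)
        return None
    pooled = table.counts[dels].sum(axis=1)
    first = dels[0]
    return _effect_from_counts(pooled, table, first, label="DEL:window")


def editing_rates(table: AlleleCountTable) -> tuple[float, float]:
    """(HDR rate, indel rate) from summed gDNA counts.

    The denominator is all classified gDNA reads plus insertion-dropped
    reads (insertions are real editing outcomes even though they are
    excluded from effect statistics); unmapped/short-span drops are not
    editing outcomes and are excluded.
    """
    gdna = table.replicate_ids("gDNA")
    if not gdna:
        raise ValueError("no gDNA replicates in table")
    counts = table.counts.loc[gdna].sum(axis=0)
    ins_dropped = int(table.dropped.loc[gdna, "insertion"].sum())
    total = int(counts.sum()) + ins_dropped
    if total == 0:
        raise ValueError("zero classified gDNA reads")
    hdr = sum(int(counts[k]) for k in counts.index if k.kind is Kind.HDR)
    dels = sum(int(counts[k]) for k in counts.index if k.kind is Kind.DEL)
    other = sum(int(counts[k]) for k in counts.index
                if k.kind in (Kind.OTHER, Kind.INS))
    return hdr / total, (dels + ins_dropped + other) / total


@dataclass(frozen=True)
class SensitivityParams:
    """Inputs for the assay sensitivity estimate.

    ``sd`` is the between-replicate standard deviation of the
    WT-normalised ratio r; ``n`` the replicates per readout group.
    """

    sd: float
    n: int = 3
    alpha: float = 0.05

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def min_detectable_change(params: SensitivityParams) -> float:
    """Smallest detectable fractional change in the WT-normalised ratio.

    Convention: the minimal detectable shift is the two-tailed critical t
    value at ``2n - 2`` degrees of freedom (the equal-n, equal-variance
    reduction of the Welch test) multiplied by the between-replicate SD of
    the ratio, i.e. a shift is detectable once it exceeds ``t_crit`` noise
    standard deviations.  A return of 0.219 means a 21.9% accessibility
    change is detectable.
    """
    if params.sd == 0:
        return 0.0
    df = 2 * params.n - 2
    tcrit = float(sps.t.ppf(1 - params.alpha / 2, df))
    return tcrit * params.sd


def pool_technical_replicates(table: AlleleCountTable,
                              parent_of: dict[str, str]) -> AlleleCountTable:
    """Collapse technical PCR replicates into their parent replicate.

    Reads from technical repeats of one tagmentation are pooled (counts
    summed) before testing, so technical repeats cannot inflate the
    degrees of freedom.
    """
    from .alleles import Replicate

    parents: dict[str, str] = {}
    readout_of = {r.replicate_id: r.readout for r in table.replicates}
    for rep in table.replicates:
        parents[rep.replicate_id] = parent_of.get(rep.replicate_id,
                                                  rep.replicate_id)
        if readout_of.get(parents[rep.replicate_id], rep.readout) != rep.readout:
            raise ValueError("technical replicate mapped across readouts")
    grouping = pd.Series(parents)
    counts = table.counts.groupby(grouping).sum()
    dropped = table.dropped.groupby(grouping).sum()
    seen, reps = set(), []
    for rep in table.replicates:
        p = parents[rep.replicate_id]
        if p not in seen:
            seen.add(p)
            reps.append(Replicate(p, rep.readout))
    order = [r.replicate_id for r in reps]
    return AlleleCountTable(table.region, reps, counts.loc[order],
                            dropped.loc[order])


def summarize_experiment(tables: Sequence[AlleleCountTable],
                         n_top_deletions: int = 2) -> pd.DataFrame:
    """One-row-per-allele-grouping summary across regions.

    Per region: the WT anchor row, every HDR allele, the pooled
    deletion-window pseudo-allele, and the top ``n_top_deletions``
    individual deletions; plus editing rates and replicate counts.
    Benjamini–Hochberg q-values are computed across all tested rows.
    Row order is deterministic (region name, then canonical allele
    order).
    """
    rows = []
    for table in sorted(tables, key=lambda t: t.region.name):
        try:
            hdr_rate, indel_rate = editing_rates(table)
        except ValueError:
            hdr_rate = indel_rate = float("nan")
        results: list[EffectResult] = [effect_size(table, WT)]
        for spec in table.region.hdr_alleles:
            key = AlleleKey(Kind.HDR, hdr_name=spec.name)
            if key in table.counts.columns:
                results.append(effect_size(table, key))
        pooled = deletion_window_effect(table) if table.window_deletions() else None
        if pooled is not None:
            results.append(pooled)
        for key in top_deletions(table, k=n_top_deletions):
            results.append(effect_size(table, key))
        for res in results:
            rows.append({
                "region": table.region.name,
                "allele": res.name,
                "kind": ("DEL_window" if res.label == "DEL:window"
                         else res.allele.kind.name),
                "effect_size": res.effect_size,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "t": res.t_stat, "df": res.df, "p": res.p_value,
                "n_atac": res.n_atac, "n_gdna": res.n_gdna,
                "hdr_rate": hdr_rate, "indel_rate": indel_rate,
            })
    summary = pd.DataFrame(rows, columns=[
        "region", "allele", "kind", "effect_size", "ci_low", "ci_high",
        "t", "df", "p", "n_atac", "n_gdna", "hdr_rate", "indel_rate"])
    summary.insert(9, "q", bh_adjust(summary["p"].to_numpy()))
    return summary


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg q-values; NaN p-values stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full(len(p), np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = sps.false_discovery_control(p[mask], method="bh")
    return q
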