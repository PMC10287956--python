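"""Effect sizes, Welch testing, editing rates and assay sensitivity."""

import numpy as np
import pytest

from atacedit import (AlleleKey, Kind, SensitivityParams, WT,
                      deletion_window_effect, editing_rates, effect_size,
                      min_detectable_change, pool_technical_replicates,
                      summarize_experiment, welch_t)

from conftest import make_count_table
from oracles import welch_reference

HDR = AlleleKey(Kind.HDR, hdr_name="snp")
D1 = AlleleKey(Kind.DEL, del_start=88, del_len=2)   # inside the ±6 window
D2 = AlleleKey(Kind.DEL, del_start=91, del_len=3)
FAR = AlleleKey(Kind.DEL, del_start=10, del_len=4)  # outside the window


# ---------------------------------------------------------------- welch_t

def test_welch_textbook_example():
    t, df, p = welch_t([1, 2, 3], [2, 4, 6])
    # hand-computed: t = -2/sqrt(5/3), df = (5/3)^2 / ((1/9)/2 + (16/9)/2)
    assert t == pytest.approx(-1.5491933, abs=1e-6)
    assert df == pytest.approx(50 / 17, abs=1e-6)
    rt, rdf, rp = welch_reference([1, 2, 3], [2, 4, 6])
    assert (t, df, p) == pytest.approx((rt, rdf, rp), abs=1e-12)


def test_welch_identical_samples():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0 and p == pytest.approx(1.0)


def test_welch_degenerate_conventions():
    assert welch_t([0, 0, 0], [0, 0, 0]) == (0.0, 4.0, 1.0)
    with pytest.warns(UserWarning, match="zero variance"):
        t, df, p = welch_t([1, 1], [2, 2])
    assert p == 0.0 and t == -np.inf


def test_welch_requires_two_observations():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


def test_welch_matches_reference_on_random_samples(rng):
    for _ in range(100):
        x = rng.normal(size=rng.integers(2, 9))
        y = rng.normal(loc=rng.normal(), size=rng.integers(2, 9))
        assert welch_t(x, y) == pytest.approx(welch_reference(x, y), abs=1e-10)


# ---------------------------------------------------------------- effect_size

def test_effect_size_halved_accessibility(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 100, 100], HDR: [25, 24, 26]},
        gdna_counts={WT: [100, 100, 100], HDR: [50, 48, 52]})
    res = effect_size(table, HDR)
    assert res.r_atac_mean == pytest.approx(0.25)
    assert res.r_gdna_mean == pytest.approx(0.50)
    assert res.effect_size == pytest.approx(0.5)
    rt, rdf, rp = welch_reference([0.25, 0.24, 0.26], [0.50, 0.48, 0.52])
    assert res.p_value == pytest.approx(rp, abs=1e-12)
    assert res.ci_low < 0.5 < res.ci_high


def test_proportional_counts_give_unit_effect(region, rng):
    gdna = {k: list(rng.integers(20, 200, size=3))
            for k in (WT, HDR, D1)}
    atac = {k: [3 * c for c in v] for k, v in gdna.items()}
    table = make_count_table(region, atac, gdna)
    for k in (HDR, D1):
        assert effect_size(table, k).effect_size == pytest.approx(1.0)


def test_wt_effect_is_one_with_undefined_p(region):
    table = make_count_table(region,
                             atac_counts={WT: [90, 110, 100]},
                             gdna_counts={WT: [50, 60, 55]})
    res = effect_size(table, WT)
    assert res.effect_size == 1.0
    assert np.isnan(res.p_value)


def test_zero_count_replicates_contribute_zero_ratio(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 100, 100], HDR: [0, 30, 30]},
        gdna_counts={WT: [100, 100, 100], HDR: [30, 30, 30]})
    res = effect_size(table, HDR)
    assert res.ratios_atac == (0.0, 0.3, 0.3)
    assert res.effect_size == pytest.approx(0.2 / 0.3)
    assert np.isfinite(res.ci_low) and res.ci_low > 0


def test_zero_wt_replicate_excluded_with_warning(region):
    table = make_count_table(
        region,
        atac_counts={WT: [0, 100, 100], HDR: [10, 30, 30]},
        gdna_counts={WT: [100, 100, 100], HDR: [30, 30, 30]})
    with pytest.warns(UserWarning, match="zero WT"):
        res = effect_size(table, HDR)
    assert res.n_atac == 2


def test_scale_invariance_per_replicate(region, rng):
    gdna = {k: list(rng.integers(20, 200, size=3)) for k in (WT, HDR)}
    atac = {k: list(rng.integers(20, 200, size=3)) for k in (WT, HDR)}
    t1 = make_count_table(region, atac, gdna)
    atac2 = {k: [v[0] * 7, v[1], v[2]] for k, v in atac.items()}
    gdna2 = {k: [v[0], v[1] * 3, v[2]] for k, v in gdna.items()}
    t2 = make_count_table(region, atac2, gdna2)
    r1, r2 = effect_size(t1, HDR), effect_size(t2, HDR)
    assert r1.effect_size == pytest.approx(r2.effect_size)
    assert r1.t_stat == pytest.approx(r2.t_stat)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_readout_symmetry_inverts_effect(region, rng):
    gdna = {k: list(rng.integers(20, 200, size=3)) for k in (WT, HDR)}
    atac = {k: list(rng.integers(20, 200, size=3)) for k in (WT, HDR)}
    fwd = effect_size(make_count_table(region, atac, gdna), HDR)
    swapped = effect_size(make_count_table(region, gdna, atac), HDR)
    assert swapped.effect_size == pytest.approx(1 / fwd.effect_size)
    assert swapped.p_value == pytest.approx(fwd.p_value)


# ---------------------------------------------------------- deletion window

def test_deletion_window_pooling_additivity(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 100], D1: [5, 5], D2: [10, 10]},
        gdna_counts={WT: [100, 100], D1: [10, 10], D2: [20, 20]})
    res = deletion_window_effect(table)
    assert res.ratios_atac == (0.15, 0.15)
    assert res.ratios_gdna == (0.30, 0.30)
    assert res.name == "DEL:window"


def test_deletion_window_single_deletion_equals_individual(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 90, 110], D1: [7, 9, 8]},
        gdna_counts={WT: [100, 90, 110], D1: [20, 18, 21]})
    pooled = deletion_window_effect(table)
    single = effect_size(table, D1)
    assert pooled.effect_size == pytest.approx(single.effect_size)
    assert pooled.p_value == pytest.approx(single.p_value)


def test_deletion_window_empty_when_all_outside(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 100], FAR: [5, 5]},
        gdna_counts={WT: [100, 100], FAR: [10, 10]})
    with pytest.warns(UserWarning, match="no deletions"):
        assert deletion_window_effect(table) is None


# ---------------------------------------------------------------- rates

def test_editing_rates_example(region):
    table = make_count_table(
        region,
        atac_counts={WT: [1, 1]},
        gdna_counts={WT: [451, 451], HDR: [25, 24], D1: [20, 20]},
        extra_dropped={("gDNA1", "insertion"): 5, ("gDNA2", "insertion"): 4})
    hdr_rate, indel_rate = editing_rates(table)
    assert hdr_rate == pytest.approx(49 / 1000)
    assert indel_rate == pytest.approx(49 / 1000)


def test_editing_rates_all_wt(region):
    table = make_count_table(region, atac_counts={WT: [10]},
                             gdna_counts={WT: [500, 500]})
    assert editing_rates(table) == (0.0, 0.0)


def test_editing_rates_all_hdr(region):
    table = make_count_table(region, atac_counts={WT: [10]},
                             gdna_counts={WT: [0, 0], HDR: [500, 500]})
    assert editing_rates(table) == (1.0, 0.0)


def test_editing_rates_requires_gdna_reads(region):
    table = make_count_table(region, atac_counts={WT: [10]},
                             gdna_counts={WT: [0, 0]})
    with pytest.raises(ValueError):
        editing_rates(table)


# ---------------------------------------------------------------- sensitivity

def test_min_detectable_change_zero_noise():
    assert min_detectable_change(SensitivityParams(sd=0.0, n=3, alpha=0.01)) == 0.0


def test_min_detectable_change_monotonicity():
    strict = min_detectable_change(SensitivityParams(0.05, 3, alpha=0.01))
    loose = min_detectable_change(SensitivityParams(0.05, 3, alpha=0.05))
    more_reps = min_detectable_change(SensitivityParams(0.05, 9, alpha=0.01))
    assert strict > loose
    assert more_reps < strict


def test_sensitivity_params_validation():
    with pytest.raises(ValueError):
        SensitivityParams(sd=-1.0)
    with pytest.raises(ValueError):
        SensitivityParams(sd=0.1, n=1)
    with pytest.raises(ValueError):
        SensitivityParams(sd=0.1, alpha=0.0)


# ---------------------------------------------------------------- summary

def test_summary_single_region_rows(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 100, 100], HDR: [25, 24, 26], D1: [5, 6, 7]},
        gdna_counts={WT: [100, 100, 100], HDR: [50, 48, 52], D1: [9, 9, 9]})
    summary = summarize_experiment([table])
    assert list(summary["kind"]) == ["WT", "HDR", "DEL_window", "DEL"]
    hdr_row = summary[summary["kind"] == "HDR"].iloc[0]
    assert hdr_row["effect_size"] == pytest.approx(0.5)
    assert set(summary.columns) >= {"region", "allele", "kind", "effect_size",
                                    "ci_low", "ci_high", "t", "df", "p", "q",
                                    "n_atac", "n_gdna", "hdr_rate", "indel_rate"}


def test_summary_multiplex_has_one_row_per_hdr_allele(rng):
    from atacedit import AmpliconRegion, Edit, HdrAlleleSpec
    from conftest import random_seq

    ref = random_seq(200, rng)
    specs = []
    for i in range(9):
        pos = 80 + i
        alt = next(b for b in "ACGT" if b != ref[pos])
        specs.append(HdrAlleleSpec(f"m{i}", (Edit(pos, ref[pos], alt),)))
    region = AmpliconRegion("multi", ref, snp_pos=84, cut_site=84,
                            hdr_alleles=specs)
    atac = {WT: [100, 100, 100]}
    gdna = {WT: [100, 100, 100]}
    for s in specs:
        k = AlleleKey(Kind.HDR, hdr_name=s.name)
        atac[k] = list(rng.integers(10, 40, size=3))
        gdna[k] = list(rng.integers(10, 40, size=3))
    summary = summarize_experiment([make_count_table(region, atac, gdna)])
    assert (summary["kind"] == "HDR").sum() == 9


def test_summary_empty_input():
    summary = summarize_experiment([])
    assert summary.empty


def test_pool_technical_replicates(region):
    table = make_count_table(
        region,
        atac_counts={WT: [100, 102, 100, 100], HDR: [20, 22, 30, 31]},
        gdna_counts={WT: [100, 100], HDR: [30, 30]})
    pooled = pool_technical_replicates(
        table, {"ATAC2": "ATAC1", "ATAC4": "ATAC3"})
    assert list(pooled.counts.index) == ["ATAC1", "ATAC3", "gDNA1", "gDNA2"]
    assert pooled.counts.loc["ATAC1", WT] == 202
    assert pooled.counts.loc["ATAC1", HDR] == 42
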