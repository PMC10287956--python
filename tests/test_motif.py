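"""Saturation-mutagenesis profiles, logo heights and PFM comparison."""

import numpy as np
import pandas as pd
import pytest

from atacedit import (AmpliconRegion, build_profile, compare_to_pfm,
                      importance_scores, logo_heights, motif_proportions,
                      read_pfm)
from atacedit.motif import BASES, PositionFrequencyMatrix, render_text_logo
from atacedit.stats import EffectResult
from atacedit.alleles import AlleleKey, Kind

from conftest import random_seq


def _res(effect, lo=None, hi=None):
    lo = lo if lo is not None else effect * 0.8
    hi = hi if hi is not None else effect * 1.25
    return EffectResult(AlleleKey(Kind.HDR, hdr_name="x"), effect, 1.0, effect,
                        lo, hi, 0.0, 4.0, 0.5, 3, 3)


@pytest.fixture
def sat_region(rng):
    return AmpliconRegion("sat", random_seq(60, rng), snp_pos=30, cut_site=30,
                          window=6)


def _full_profile(region, positions, effect_of=None):
    """Profile with all three substitutions measured at each position."""
    results = {}
    for p in positions:
        for b in BASES:
            if b == region.ref_seq[p]:
                continue
            e = effect_of(p, b) if effect_of else 0.5
            results[(p, b)] = _res(e)
    return build_profile(results, region)


def test_profile_shape_and_wt_cells(sat_region):
    positions = list(range(20, 29))
    prof = _full_profile(sat_region, positions)
    assert prof.effect.shape == (9, 4)
    for p in positions:
        assert prof.effect.loc[p, sat_region.ref_seq[p]] == 1.0
        assert not prof.mask.loc[p].any()


def test_profile_rejects_duplicates_and_wt_results(sat_region):
    p = 25
    wt = sat_region.ref_seq[p]
    alt = next(b for b in BASES if b != wt)
    with pytest.raises(ValueError, match="duplicate"):
        build_profile({(p, alt): _res(0.5), (p, alt.lower()): _res(0.6)},
                      sat_region)
    with pytest.raises(ValueError, match="WT"):
        build_profile({(p, wt): _res(0.5)}, sat_region)


def test_empty_profile(sat_region):
    prof = build_profile({}, sat_region)
    assert prof.effect.empty


def test_logo_heights_square_rule(sat_region):
    prof = _full_profile(sat_region, [20, 21], effect_of=lambda p, b: 0.9)
    h = logo_heights(prof)
    wt = sat_region.ref_seq[20]
    assert h.loc[20, wt] == 1.0
    for b in BASES:
        if b != wt:
            assert h.loc[20, b] == pytest.approx(0.81)


def test_logo_heights_masked_cells_zero(sat_region):
    p = 22
    alt = [b for b in BASES if b != sat_region.ref_seq[p]]
    results = {(p, alt[0]): _res(0.7)}
    prof = build_profile(results, sat_region,
                         masked={(p, alt[1]), (p, alt[2])})
    h = logo_heights(prof)
    assert h.loc[p, alt[1]] == 0.0 and h.loc[p, alt[2]] == 0.0
    assert h.loc[p, alt[0]] == pytest.approx(0.49)


def test_importance_is_inverse_effect(sat_region):
    prof = _full_profile(sat_region, [20], effect_of=lambda p, b: 0.25)
    imp = importance_scores(prof)
    wt = sat_region.ref_seq[20]
    assert imp.loc[20, wt] == 1.0
    assert all(imp.loc[20, b] == pytest.approx(4.0)
               for b in BASES if b != wt)


def test_motif_proportions_arithmetic(sat_region):
    # effects (WT first in ACGT order determined by ref base)
    p = 20
    wt = sat_region.ref_seq[p]
    alts = [b for b in BASES if b != wt]
    effects = dict(zip(alts, [0.1, 0.9, 0.2]))
    prof = _full_profile(sat_region, [p],
                         effect_of=lambda _, b: effects[b])
    props = motif_proportions(prof)
    total = 1.0 + 0.1 + 0.9 + 0.2
    assert props.loc[p, wt] == pytest.approx(1.0 / total)
    assert props.loc[p].sum() == pytest.approx(1.0, abs=1e-12)


def test_motif_proportions_uniform_when_equal(sat_region):
    prof = _full_profile(sat_region, [20, 21], effect_of=lambda p, b: 1.0)
    props = motif_proportions(prof)
    assert np.allclose(props.to_numpy(), 0.25)


def test_motif_proportions_exclude_masked_positions(sat_region):
    p_ok, p_masked = 20, 21
    results = {}
    for p in (p_ok, p_masked):
        for b in BASES:
            if b != sat_region.ref_seq[p]:
                results[(p, b)] = _res(0.5)
    del results[(p_masked, next(b for b in BASES
                                if b != sat_region.ref_seq[p_masked]))]
    prof = build_profile(results, sat_region)
    props = motif_proportions(prof)
    assert list(props.index) == [p_ok]
    rows = motif_proportions(prof).sum(axis=1)
    assert np.allclose(rows, 1.0, atol=1e-12)


def _pfm_from_props(props):
    return PositionFrequencyMatrix(
        "t", props.reset_index(drop=True) * 100.0)


def test_compare_identical_proportions_r_one(sat_region):
    prof = _full_profile(sat_region, list(range(20, 26)),
                         effect_of=lambda p, b: 0.2 + 0.1 * (p % 3))
    props = motif_proportions(prof)
    pfm = _pfm_from_props(props)
    r, cells = compare_to_pfm(props, pfm, offset=20)
    assert r == pytest.approx(1.0)
    assert len(cells) == 6 * 4


def test_compare_uniform_profile_degenerate_nan(sat_region):
    prof = _full_profile(sat_region, [20, 21, 22], effect_of=lambda p, b: 1.0)
    props = motif_proportions(prof)
    counts = pd.DataFrame(np.array([[8, 1, 1, 0], [1, 7, 1, 1], [0, 0, 9, 1]],
                                   dtype=float), columns=list(BASES))
    r, _ = compare_to_pfm(props, PositionFrequencyMatrix("t", counts), offset=20)
    assert np.isnan(r)


def test_compare_invariant_to_pfm_rescaling(sat_region, rng):
    prof = _full_profile(sat_region, list(range(20, 25)),
                         effect_of=lambda p, b: float(0.1 + 0.8 * ((p * 7 + ord(b)) % 5) / 5))
    props = motif_proportions(prof)
    counts = pd.DataFrame(rng.integers(1, 50, size=(5, 4)).astype(float),
                          columns=list(BASES))
    r1, _ = compare_to_pfm(props, PositionFrequencyMatrix("t", counts), offset=20)
    r2, _ = compare_to_pfm(props, PositionFrequencyMatrix("t", counts * 37.5),
                           offset=20)
    assert r1 == pytest.approx(r2)


def test_compare_reverse_strand_palindromic_pfm(sat_region):
    prof = _full_profile(sat_region, list(range(20, 24)),
                         effect_of=lambda p, b: 0.2 + 0.05 * (p - 20))
    props = motif_proportions(prof)
    pal = pd.DataFrame(np.array([[5, 2, 2, 1], [1, 4, 4, 1],
                                 [1, 4, 4, 1], [1, 2, 2, 5]], dtype=float),
                       columns=list(BASES))
    pfm = PositionFrequencyMatrix("pal", pal)
    assert pfm.reverse_complement().counts.equals(pfm.counts)
    r_fwd, _ = compare_to_pfm(props, pfm, offset=20, strand="+")
    r_rev, _ = compare_to_pfm(props, pfm, offset=20, strand="-")
    assert r_fwd == pytest.approx(r_rev)


def test_compare_requires_overlap(sat_region):
    prof = _full_profile(sat_region, [20, 21])
    props = motif_proportions(prof)
    counts = pd.DataFrame(np.ones((4, 4)), columns=list(BASES))
    with pytest.raises(ValueError, match="overlap"):
        compare_to_pfm(props, PositionFrequencyMatrix("t", counts), offset=500)


JASPAR_TEXT = """>MA0001.1 TEST
A  [ 10  2  0 ]
C  [  1  5  1 ]
G  [  2  2 14 ]
T  [  0  4  0 ]
"""

RAW_PFM_TEXT = """10 2 0
1 5 1
2 2 14
0 4 0
"""


def test_read_pfm_both_dialects(tmp_path):
    j = tmp_path / "m.jaspar"
    j.write_text(JASPAR_TEXT)
    p = tmp_path / "m.pfm"
    p.write_text(RAW_PFM_TEXT)
    pfm_j = read_pfm(j)
    pfm_p = read_pfm(p)
    assert pfm_j.length == 3
    assert pfm_j.counts.equals(pfm_p.counts)
    assert pfm_j.proportions().loc[0, "A"] == pytest.approx(10 / 13)


def test_text_logo_renders_each_position(sat_region):
    prof = _full_profile(sat_region, [20, 21, 22])
    logo = render_text_logo(logo_heights(prof))
    lines = logo.splitlines()
    assert len(lines) == 12  # 10 height rows + rule + position labels
    assert lines[-1].split() == ["0", "1", "2"]
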