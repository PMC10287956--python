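import numpy as np
import pytest

from atacedit import AmpliconRegion, Edit, HdrAlleleSpec


def random_seq(n: int, rng) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def region(rng):
    """A 180-bp amplicon with one substitution HDR allele near the cut."""
    ref = random_seq(180, rng)
    alt = "A" if ref[90] != "A" else "G"
    hdr = HdrAlleleSpec("snp", (Edit(90, ref[90], alt),))
    return AmpliconRegion("reg1", ref, snp_pos=90, cut_site=93,
                          hdr_alleles=[hdr])


def make_count_table(region, atac_counts, gdna_counts, extra_dropped=None):
    """Build an AlleleCountTable from dicts of allele -> per-replicate counts."""
    import pandas as pd

    from atacedit.alleles import (AlleleCountTable, Replicate, WT,
                                  DROP_REASONS)

    n_atac = len(next(iter(atac_counts.values())))
    n_gdna = len(next(iter(gdna_counts.values())))
    reps = ([Replicate(f"ATAC{i+1}", "ATAC") for i in range(n_atac)]
            + [Replicate(f"gDNA{i+1}", "gDNA") for i in range(n_gdna)])
    keys = sorted(set(atac_counts) | set(gdna_counts) | {WT})
    rows = []
    for i in range(n_atac):
        rows.append([atac_counts.get(k, [0] * n_atac)[i] for k in keys])
    for i in range(n_gdna):
        rows.append([gdna_counts.get(k, [0] * n_gdna)[i] for k in keys])
    counts = pd.DataFrame(rows, index=pd.Index([r.replicate_id for r in reps],
                                               name="replicate"), columns=keys)
    dropped = pd.DataFrame(0, index=counts.index, columns=list(DROP_REASONS))
    if extra_dropped:
        for (rep, reason), v in extra_dropped.items():
            dropped.loc[rep, reason] = v
    return AlleleCountTable(region, reps, counts, dropped)
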