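import numpy as np
import pandas as pd
import pytest

from slrscape import synthetic_data as sd
from slrscape.sexlink_scan import VariantTable


@pytest.fixture(scope="session")
def small_sex_bundle():
    """2-Mb sex chromosome with a 0.5-1.5 Mb SLR and strata boundary at 1 Mb."""
    cfg = sd.single_chrom_config(
        2_000_000, seed=7,
        slr_interval=(500_000, 1_500_000), strata_boundary=1_000_000,
        pch_mean_len=400_000, pch_sd_len=50_000, pch_min_len=200_000,
        cen_positions=[0.5],
    )
    return sd.gen_genome(cfg)


@pytest.fixture(scope="session")
def zigzag_track_bundle():
    """Whole-genome (24-chromosome) bundle in track-only mode."""
    return sd.gen_genome(sd.zigzag_config(seed=7, track_only=True))


def make_variant_table(genotypes, n_males=None, chrom="chr1", positions=None):
    """VariantTable from a plain int matrix (sites x samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples = g.shape[1]
    n_males = n_samples // 2 if n_males is None else n_males
    samples = [f"M{i}" for i in range(n_males)] + [
        f"F{i}" for i in range(n_samples - n_males)
    ]
    sex = {s: ("male" if s.startswith("M") else "female") for s in samples}
    pos = positions if positions is not None else np.arange(1, g.shape[0] + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"}
    )
    return VariantTable(sites, g, samples, sex)
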