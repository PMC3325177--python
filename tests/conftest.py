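import numpy as np
import pandas as pd
import pytest

from popdiff.frequencies import FrequencyTable, RegionMap


def make_table(rows):
    """Build a FrequencyTable from (rsid, a, b, population, freq_a, n_chrom) tuples."""
    df = pd.DataFrame(
        rows, columns=["rsid", "allele_a", "allele_b", "population", "freq_a", "n_chromosomes"]
    )
    df["chrom"] = "1"
    df["pos"] = df.groupby("rsid").ngroup() * 100 + 1
    return FrequencyTable(df)


@pytest.fixture
def region_map():
    return RegionMap(
        {"African": ["YRI", "LWK"], "European": ["CEU", "TSI"], "Asian": ["CHB", "JPT"]}
    )


@pytest.fixture
def toy_table():
    """Three regions x two populations, a handful of SNPs with known frequencies."""
    rows = []
    freqs = {
        # rsid: (YRI, LWK, CEU, TSI, CHB, JPT)
        "rs1": (0.80, 0.78, 0.50, 0.50, 0.20, 0.22),  # strong Africa-high/Asia-low cline
        "rs2": (0.50, 0.52, 0.50, 0.50, 0.50, 0.48),
        "rs3": (0.30, 0.32, 0.50, 0.52, 0.70, 0.72),  # reversed cline
        "rs4": (0.55, 0.53, 0.51, 0.49, 0.47, 0.45),
        "rs5": (0.60, 0.58, 0.50, 0.50, 0.40, 0.42),
        "rs6": (0.52, 0.50, 0.50, 0.52, 0.50, 0.48),
    }
    pops = ["YRI", "LWK", "CEU", "TSI", "CHB", "JPT"]
    for rsid, fs in freqs.items():
        for pop, f in zip(pops, fs):
            rows.append((rsid, "A", "G", pop, f, 100))
    return make_table(rows)


@pytest.fixture(scope="session")
def null_corpus():
    """A no-cline corpus: genome drift only, used by calibration-style tests."""
    import popdiff

    cfg = popdiff.SimulationConfig(
        n_genome_snps=2000, n_disease_snps=10, delta_high=0.0, delta_low=0.0, seed=11
    )
    return popdiff.simulate_corpus(cfg)


@pytest.fixture(scope="session")
def cline_corpus():
    """Default study conditions: 10 disease loci with a +0.10/-0.10 cline."""
    import popdiff

    cfg = popdiff.SimulationConfig(n_genome_snps=2000, seed=13)
    return popdiff.simulate_corpus(cfg)
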