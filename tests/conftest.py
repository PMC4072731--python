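import pytest

from poolex import syndata

# Worked-example allele-depth rows from a published two-population pooled
# RNA-seq experiment (allele-A/allele-B read counts pooled per treatment,
# with the allele-B frequencies as printed, to 2 decimals).
REFERENCE_DAE_ROWS = {
    "Eucgr.E01218": {
        "pos": 13097458,
        "region": "UTR5",
        "trial1_high": (830, 917),
        "trial1_low": (941, 290),
        "trial2_high": (1090, 934),
        "trial2_low": (1821, 275),
        "printed_freqs": (0.52, 0.24, 0.46, 0.13),
    },
    "Eucgr.K02930": {
        "pos": 37329597,
        "region": "UTR3",
        "trial1_high": (2373, 1057),
        "trial1_low": (1962, 337),
        "trial2_high": (2469, 916),
        "trial2_low": (3386, 166),
        "printed_freqs": (0.31, 0.15, 0.27, 0.05),
    },
}

# Published sequencing totals: reads summed over the six bulk libraries of
# each trial, used for the CPM <-> read-count correspondence.
TRIAL_TOTAL_READS = {"trial1": 430e6, "trial2": 286e6}
TRIAL_EXPECTED_READS_PER_CPM = {"trial1": 70, "trial2": 50}


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimConfig(
        n_genes=80, genes_per_chrom=40, mean_lib_size=80_000, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syndata.generate_dataset(small_config)
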