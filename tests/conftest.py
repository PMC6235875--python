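import pytest

from seedvar.synthgen import SynthConfig, generate_dataset, write_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """Miniature study: fast enough for per-module tests, still exercising
    every planted variant category."""
    return SynthConfig(
        seed=7,
        n_chroms=2,
        chrom_length=300_000,
        n_genes=30,
        n_diff_snp=300,
        n_diff_mnp=20,
        n_diff_indel=40,
        n_diff_complex=25,
        n_confound_variants=40,
        n_density_clusters=4,
        n_seed_specific=10,
        n_candidate_genes=5,
        n_qtls=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("synth_small")
    write_dataset(small_dataset, d)
    return d
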