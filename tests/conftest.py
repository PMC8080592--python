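import pytest
from hypothesis import settings

from epiflock.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dataset():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for tests that re-simulate repeatedly."""
    return SimulationConfig(
        seed=7,
        n_chroms=1,
        chrom_length=60_000,
        n_genes=10,
        n_lnc_candidates=16,
        n_fail_single_exon=2,
        n_fail_short=1,
        n_fail_known_overlap=2,
        n_fail_low_expression=2,
        n_fail_coding=2,
        n_planted_dmrs=4,
        n_planted_targets=4,
        n_planted_de=4,
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """Hand-written 3-gene, 5-transcript GTF (1-based inclusive on disk)."""
    text = "\n".join(
        [
            'chr1\ttoy\tgene\t101\t500\t.\t+\t.\tgene_id "gA"; biotype "coding";',
            'chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\texon\t301\t500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\texon\t101\t500\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t2";',
            'chr1\ttoy\tgene\t1001\t2000\t.\t-\t.\tgene_id "gB"; biotype "coding";',
            'chr1\ttoy\texon\t1001\t1400\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\texon\t1601\t2000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\texon\t1001\t2000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t2";',
            'chr2\ttoy\tgene\t51\t250\t.\t+\t.\tgene_id "gC"; biotype "lncRNA";',
            'chr2\ttoy\texon\t51\t250\t.\t+\t.\tgene_id "gC"; transcript_id "gC.t1";',
        ]
    )
    path = tmp_path / "toy.gtf"
    path.write_text(text + "\n")
    return path
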