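import numpy as np
import pytest

from nbipscan import RunConfig, SimConfig, run_all, simulate


class FakeSeqSlice(str):
    """Mimics the object pyfaidx returns for genome[chrom][a:b]."""

    @property
    def seq(self) -> str:
        return str(self)


class FakeChrom:
    def __init__(self, seq: str):
        self._seq = seq

    def __getitem__(self, sl):
        return FakeSeqSlice(self._seq[sl])

    def __len__(self):
        return len(self._seq)


class FakeGenome(dict):
    """In-memory stand-in for a pyfaidx.Fasta handle."""

    def __init__(self, seqs: dict[str, str]):
        super().__init__({name: FakeChrom(s) for name, s in seqs.items()})


@pytest.fixture
def fake_genome():
    return FakeGenome


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Default synthetic fixture, seed 1."""
    out = tmp_path_factory.mktemp("sim")
    simulate(SimConfig(rng_seed=1), out)
    return out


def make_run_config(sim_dir, **kw) -> RunConfig:
    base = dict(
        fasta=str(sim_dir / "genome.fa"),
        gtf=str(sim_dir / "annotation.gtf"),
        contigs=str(sim_dir / "contigs.bed12"),
        expression=str(sim_dir / "expression.tsv"),
        cage=str(sim_dir / "cage.bed"),
        h3k4me3=str(sim_dir / "h3k4me3.bedgraph"),
        input_track=str(sim_dir / "input.bedgraph"),
        methylation=str(sim_dir / "methylation.bedgraph"),
        phastcons=str(sim_dir / "phastcons.bedgraph"),
        rp=str(sim_dir / "rp.bedgraph"),
        peaks=str(sim_dir / "h3k4me3_peaks.bed"),
        polya=str(sim_dir / "polya_sites.bed"),
        alt_contigs=str(sim_dir / "alt_contigs.bed12"),
        junctions=str(sim_dir / "junctions.tsv"),
        pwms=str(sim_dir / "matrices.dat"),
        neuron_flags=str(sim_dir / "neuron_flags.tsv"),
        n_perm_age=200,
        n_perm_junction=100,
        seed=1,
    )
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture
def run_config_factory():
    return make_run_config


@pytest.fixture(scope="session")
def pipeline_results(sim_dir, tmp_path_factory):
    """One full pipeline run on the default fixture, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    return run_all(make_run_config(sim_dir), out), out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
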