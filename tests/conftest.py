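import numpy as np
import pytest

from homeobias import PipelineConfig, SynthConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic hexaploid bundle (60 groups, 5 clusters, 4 pairs,
    10 orphans; planted |log2FC| = 2, noise sigma 0.25, n = 3)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_dataset(SynthConfig(seed=11), outdir)


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        protein_fasta=str(default_bundle.protein_fasta),
        gff3=str(default_bundle.gff3),
        genome_fasta=str(default_bundle.genome_fasta),
        vcf=str(default_bundle.vcf),
        fpkm_tsv=str(default_bundle.fpkm_tsv),
        design_tsv=str(default_bundle.design_tsv),
        outdir=str(outdir),
        seed=11,
    )
    report = run_pipeline(cfg)
    return cfg, report


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_protein(rng, length):
    from homeobias.features import AMINO_ACIDS

    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
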