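import pytest

from srslnc.synthetic_data import SyntheticConfig, generate_dataset, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (seed 17), shared across the session."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def dataset_dir(dataset, tmp_path_factory):
    """The default dataset written out as files."""
    out = tmp_path_factory.mktemp("synth")
    write_dataset(dataset, out)
    return out


@pytest.fixture(scope="session")
def pipeline_run(dataset_dir, tmp_path_factory):
    """One full pipeline run over the default dataset."""
    from srslnc.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("results")
    cfg = PipelineConfig(
        gtf=str(dataset_dir / "transcripts.gtf"),
        repeats=str(dataset_dir / "simple_repeats.tsv"),
        chrom_info=str(dataset_dir / "chrom_info.tsv"),
        genome=str(dataset_dir / "genome.fa"),
        counts=str(dataset_dir / "counts.tsv"),
        tpm=str(dataset_dir / "tpm.tsv"),
        motifs=str(dataset_dir / "motifs.meme"),
        peaks=str(dataset_dir / "clip_peaks.bed"),
        outdir=str(out),
    )
    report = run_pipeline(cfg)
    return cfg, report, out
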