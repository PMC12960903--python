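import pytest

from orfannotate.fixtures import generate_fixture, generate_training_sets
from orfannotate.scoring import CodingModel, train_model


@pytest.fixture(scope="session")
def ld_scorer():
    """Length-dominant diagnostic scorer: probability L/(L+100), cutoff 0.35."""
    return CodingModel.length_dominant()


@pytest.fixture(scope="session")
def fixture50(tmp_path_factory):
    """50 synthetic transcripts, both strands, 1-8 exons, written to disk."""
    out = tmp_path_factory.mktemp("fixture50")
    return generate_fixture(50, exon_count_range=(1, 8), seed=11, out_dir=out)


@pytest.fixture(scope="session")
def trained_model():
    """Small model trained on the synthetic separable training sets."""
    coding, noncoding = generate_training_sets(n_per_class=80, seed=5)
    return train_model(coding, noncoding, seed=5, cutoff=0.5, species_label="fixture")


@pytest.fixture()
def run_fixture_pipeline(tmp_path, ld_scorer):
    """Run the full pipeline on a Fixture object with the diagnostic scorer."""
    from orfannotate.pipeline import PipelineConfig, run

    def _run(fixture, **overrides):
        cfg = PipelineConfig(
            gtf_path=str(fixture.gtf_path),
            genome_path=str(fixture.genome_path),
            model_selector=overrides.pop("model_selector", ld_scorer),
            uorf_min_prob=overrides.pop("uorf_min_prob", 0.01),
            output_dir=str(tmp_path / overrides.pop("output_dir", "out")),
            **overrides,
        )
        return run(cfg), cfg

    return _run
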