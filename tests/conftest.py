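import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One full synthetic study, shared across the suite."""
    from crypticorf.pipeline import run_study

    return run_study(seed=1)


@pytest.fixture(scope="session")
def reference(study):
    return study.reference


@pytest.fixture()
def toy_genome():
    from crypticorf.annotation import GenomeBuild

    #            0         1         2
    #            0123456789012345678901234567890
    return GenomeBuild({"chrT": "GGATGAAATAATTTCCCGGGAAACCCTTTGG"})


def make_transcript(**kw):
    from crypticorf.annotation import TranscriptModel

    defaults = dict(
        transcript_id="tx1",
        gene_id="g1",
        gene_name="G1",
        contig="chrT",
        strand="+",
        exons=((0, 31),),
        cds_span=None,
        biotype="other",
    )
    defaults.update(kw)
    return TranscriptModel(**defaults)


@pytest.fixture()
def make_tx():
    return make_transcript
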