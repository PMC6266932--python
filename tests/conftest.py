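import pytest

from orthonet.fixtures import FixtureConfig, generate_fixture
from orthonet.io import SequenceLevel, SimilarityHit


def make_hit(
    q,
    s,
    level=SequenceLevel.GENE,
    score=100.0,
    evalue=1e-20,
    pident=80.0,
    qlen=1000,
    slen=1000,
    q_iv=None,
    s_iv=None,
    alen=None,
):
    """Construct a SimilarityHit with sensible defaults for tests."""
    q_iv = tuple(q_iv) if q_iv else ((1, min(500, qlen)),)
    s_iv = tuple(s_iv) if s_iv else ((1, min(500, slen)),)
    if alen is None:
        alen = q_iv[0][1] - q_iv[0][0] + 1
    return SimilarityHit(
        query_id=q,
        subject_id=s,
        level=level,
        percent_identity=pident,
        alignment_length=alen,
        bit_score=score,
        e_value=evalue,
        query_length=qlen,
        subject_length=slen,
        query_intervals=q_iv,
        subject_intervals=s_iv,
    )


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Default planted dataset shared across tests (read-only)."""
    d = tmp_path_factory.mktemp("fixture")
    truth, paths = generate_fixture(d, FixtureConfig(), seed=11)
    return truth, d


@pytest.fixture(scope="session")
def planted_run(planted):
    """One full pipeline run on the planted dataset (read-only)."""
    import warnings

    from orthonet.pipeline import (
        ClusteringParams,
        fixture_pipeline_config,
        run_pipeline,
    )

    truth, d = planted
    config = fixture_pipeline_config(
        d, d / "out", clustering=ClusteringParams(k=4, seed=11, k_range=())
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config)
    return truth, result
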