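"""Shared fixtures: one full study-scale pipeline run reused across the
suite (it takes ~1 minute), plus a fast small-genome configuration."""

import pytest

from bacmap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def pipe(tmp_path_factory):
    """The seeded 2-Mbp, three-library x 10x study run, with artifacts."""
    out = tmp_path_factory.mktemp("study_run")
    return run_pipeline(PipelineConfig(seed=1), out)


@pytest.fixture(scope="session")
def small_cfg_kwargs():
    """A fast (~4 s) configuration for end-to-end and CLI tests."""
    return dict(
        seed=5,
        genome_length=600_000,
        coverage=8,
        n_ssr_markers=4,
        n_cosii_markers=1,
    )


def clone_intervals(result):
    """clone_id -> (true_start, true_end) for every simulated clone."""
    return {c.clone_id: (c.true_start, c.true_end) for c in result.clones}


def overlap_bp(iv1, iv2):
    return max(0, min(iv1[1], iv2[1]) - max(iv1[0], iv2[0]))
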