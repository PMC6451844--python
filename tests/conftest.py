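import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: seed for every randomised fixture in the suite
SEED = 11


@pytest.fixture(scope="session")
def study_inputs(tmp_path_factory):
    """A full synthetic study at the default conditions, written once."""
    from conmir.synthetic import simulate_all

    out = tmp_path_factory.mktemp("study")
    paths = simulate_all(out, seed=SEED)
    return paths


@pytest.fixture(scope="session")
def small_inputs(tmp_path_factory):
    """A miniature synthetic study for fast pipeline-level tests."""
    from conmir.synthetic import SimConfig, simulate_all

    cfg = SimConfig(
        n_families=4,
        n_species=2,
        n_planted=6,
        n_scaffolds=2,
        scaffold_length=3000,
        depth_mean=8.0,
        n_cleavage_sites=4,
        n_translation_sites=1,
        n_extra_transcripts=3,
        transcript_length=300,
    )
    out = tmp_path_factory.mktemp("small")
    paths = simulate_all(out, seed=SEED, config=cfg)
    return cfg, paths


def make_run_config(paths, out_dir, seed=SEED):
    from conmir.pipeline import RunConfig

    return RunConfig(
        reads=str(paths["reads"]),
        mature=str(paths["mature"]),
        genome=str(paths["genome"]),
        transcripts=str(paths["transcripts"]),
        go_annotations=str(paths["go"]),
        stress_genes=str(paths["stress_genes"]),
        class_references={
            k.split("_", 1)[1]: str(v) for k, v in paths.items() if k.startswith("class_")
        },
        out_dir=str(out_dir),
        seed=seed,
    )
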