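"""Shared fixtures: one synthetic scene and one full pipeline run per session."""

import pytest

from hicrewire import PipelineConfig, generate_dataset, run_all

SCENE_SEED = 1


@pytest.fixture(scope="session")
def scene(tmp_path_factory):
    """Default synthetic scene (2 chromosomes x 20 Mb, 3 replicates x 3 conditions)."""
    path = tmp_path_factory.mktemp("scene") / "data"
    manifest = generate_dataset(path, seed=SCENE_SEED)
    return path, manifest


@pytest.fixture(scope="session")
def pipeline_run(scene, tmp_path_factory):
    """Full pipeline results + output directory for the default scene."""
    scene_dir, manifest = scene
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig.from_yaml(scene_dir / "config.yaml")
    results = run_all(cfg, out)
    return results, out, manifest
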