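import numpy as np
import pytest

from fcseg.config import PipelineConfig
from fcseg.phantom import PhantomSpec, fat_sector_roi, make_phantom
from fcseg.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact phantom for fast per-module tests."""
    return PhantomSpec(
        size=(128, 128),
        centre=(64.0, 64.0),
        arm_radius=48.0,
        fat_thickness=14.0,
        bone_centre=(64.0, 64.0),
        bone_radius=7.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return make_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def default_phantom_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def default_phantom(default_phantom_spec):
    return make_phantom(default_phantom_spec)


@pytest.fixture(scope="session")
def phantom_training_roi(default_phantom_spec):
    """Clean fat sector opposite the acoustic shadow, for stats training."""
    return fat_sector_roi(default_phantom_spec)


def seed_in_fat(spec: PhantomSpec, angle_deg: float) -> tuple[int, int]:
    """A seed pixel at mid-thickness of the fat ring at the given angle."""
    radius = spec.arm_radius - spec.fat_thickness / 2.0
    theta = np.deg2rad(angle_deg)
    return (
        int(round(spec.centre[0] + radius * np.sin(theta))),
        int(round(spec.centre[1] + radius * np.cos(theta))),
    )


@pytest.fixture(scope="session")
def pipeline_runs(default_phantom, default_phantom_spec, phantom_training_roi):
    """Full pipeline on the default phantom from two distinct fat seeds.

    Session-scoped: this is the expensive end-to-end computation shared by
    the pipeline and acceptance tests.
    """
    image, labels, truth = default_phantom
    config = PipelineConfig()
    seeds = [seed_in_fat(default_phantom_spec, 270.0), seed_in_fat(default_phantom_spec, 0.0)]
    results = [
        run_pipeline(image, [seed], config, train_roi=phantom_training_roi)
        for seed in seeds
    ]
    return {"results": results, "seeds": seeds, "truth": truth, "labels": labels}
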