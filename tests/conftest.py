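import pytest

from repromptseg import (
    BackgroundRegion,
    LabelSchema,
    ObjectSpec,
    SceneConfig,
    generate_scene,
)


@pytest.fixture(scope="session")
def schema():
    return LabelSchema({0: "background", 1: "anatomy", 2: "grasper", 3: "hook"})


@pytest.fixture(scope="session")
def entry_scene():
    """64x64, 60 frames: static disk (class 2) + disk (class 3) entering at 20."""
    cfg = SceneConfig(
        H=64, W=64, T=60,
        objects=(
            ObjectSpec(2, "disk", (6,), (20, 12), (0, 0), 0, None),
            ObjectSpec(3, "disk", (5,), (45, 8), (0, 1), 20, None),
        ),
        texture_seed=1, noise_seed=2,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def exit_scene():
    """Moving disk (class 3) leaves the scene at frame 30."""
    cfg = SceneConfig(
        H=64, W=64, T=60,
        objects=(
            ObjectSpec(2, "disk", (6,), (20, 12), (0, 0), 0, None),
            ObjectSpec(3, "disk", (5,), (45, 8), (0, 1), 0, 30),
        ),
        texture_seed=1, noise_seed=2,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def static_scene():
    """Zero-motion scene: one static disk per class on a labelled region."""
    cfg = SceneConfig(
        H=48, W=48, T=20,
        background_regions=(BackgroundRegion(1, (0, 0, 48, 24)),),
        objects=(
            ObjectSpec(2, "disk", (5,), (14, 34), (0, 0), 0, None),
            ObjectSpec(3, "rectangle", (8, 10), (34, 34), (0, 0), 0, None),
        ),
        texture_seed=3, noise_seed=4,
    )
    return generate_scene(cfg)
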