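"""Shared fixtures: small synthetic slides and a quickly trained segmenter.

Everything is generated at test time from fixed seeds; no binary fixtures
are stored. Sizes are deliberately small (quarter-scale roots, 256-px
patches) so the whole suite stays fast while exercising the same code paths
as full-scale runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from peridermtk import model as md
from peridermtk import postprocess as pp
from peridermtk import synthetic_data as sd

SMALL_CANVAS = (3000, 1800)

#: postprocess config scaled to the small fixtures (roots ~50 px wide)
SMALL_PP = pp.PostprocessConfig(min_root_area=2000)


def small_specs(n_roots: int, base_seed: int) -> list[sd.SyntheticRootSpec]:
    rng = np.random.default_rng(base_seed)
    return [
        sd.SyntheticRootSpec(
            total_length=float(rng.uniform(2000, 2600)),
            width=float(rng.uniform(45, 60)),
            periderm_fraction=float(rng.uniform(0.35, 0.55)),
            curvature_amplitude=float(rng.uniform(40, 80)),
            curvature_period=float(rng.uniform(1500, 2500)),
            lateral_root_count=int(rng.integers(0, 2)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(n_roots)
    ]


@pytest.fixture(scope="session")
def small_slide() -> sd.SyntheticSlide:
    """A 3000x1800 slide with two roots of known analytic lengths."""
    return sd.generate_slide(
        n_roots=2, specs=small_specs(2, 5), seed=5, canvas=SMALL_CANVAS, slide_id="fix1"
    )


@pytest.fixture(scope="session")
def straight_slide() -> sd.SyntheticSlide:
    """A single straight root (no curvature): arc positions == row offsets."""
    spec = sd.SyntheticRootSpec(
        total_length=2400, width=50, periderm_fraction=0.6,
        curvature_amplitude=0.0, lateral_root_count=0, seed=11,
    )
    return sd.generate_slide(
        n_roots=1, specs=[spec], seed=11, canvas=(2800, 600), slide_id="straight"
    )


@pytest.fixture(scope="session")
def trained_fixture_model(small_slide) -> tuple[md.TrainedModel, md.TrainHistory]:
    """A segmenter trained once per session on small synthetic patches."""
    second = sd.generate_slide(
        n_roots=2, specs=small_specs(2, 6), seed=6, canvas=SMALL_CANVAS, slide_id="fix2"
    )
    patches, masks = sd.make_patch_dataset([small_slide, second], patch_size=256)
    model, history = md.train(
        patches,
        masks,
        md.ModelConfig(hidden_layer_sizes=(64,)),
        md.TrainConfig(epochs=25, seed=0, val_sample_size=30000),
    )
    return model, history
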