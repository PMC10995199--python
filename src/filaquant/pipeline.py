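"""End-to-end convenience workflows tying the modules together."""

from __future__ import annotations

import pandas as pd

from .cohort import summarize_condition
from .morphometry import MorphometryConfig, classify_cells, measure_objects
from .segmentation import SegmentationConfig, segment_image
from .simulate import ImageSimConfig, generate_image_set

__all__ = ["classify_image", "cells_table", "simulate_and_classify"]


def classify_image(nuclear, reporter, seg_config=None, morph_config=None):
    """Segment one field and classify every detected cell.

    Returns ``(classifications, objects, cells)``.
    """
    seg_cfg = seg_config or SegmentationConfig()
    morph_cfg = morph_config or MorphometryConfig(pixel_size_um=seg_cfg.pixel_size_um)
    cells, object_masks, _ = segment_image(nuclear, reporter, seg_cfg)
    objects = measure_objects(object_masks, morph_cfg)
    classifications = classify_cells(
        objects, cell_ids=[c.cell_id for c in cells], config=morph_cfg
    )
    return classifications, objects, cells


def cells_table(classifications, image_id, condition) -> pd.DataFrame:
    """Flatten per-cell classifications into the tidy cells table."""
    return pd.DataFrame(
        [
            {
                "image_id": image_id,
                "condition": condition,
                "cell_id": c.cell_id,
                "n_objects": c.n_objects,
                "d_class": c.d_class,
                "perimeter_class": c.perimeter_class,
            }
            for c in classifications
        ]
    )


def simulate_and_classify(
    config: ImageSimConfig,
    n_images: int,
    condition: str = "simulated",
    seg_config=None,
    morph_config=None,
):
    """Simulate an image set, run the full pipeline, summarise the condition.

    Returns ``(summary, cells_df)`` where ``summary`` is the single
    :class:`~filaquant.cohort.ConditionSummary` for the simulated condition.
    """
    seg_cfg = seg_config or SegmentationConfig(pixel_size_um=config.pixel_size_um)
    morph_cfg = morph_config or MorphometryConfig(pixel_size_um=config.pixel_size_um)
    frames = []
    for i, sim in enumerate(generate_image_set(config, n_images)):
        cls, _, _ = classify_image(sim.nuclear, sim.reporter, seg_cfg, morph_cfg)
        frames.append(cells_table(cls, image_id=i, condition=condition))
    cells_df = pd.concat(frames, ignore_index=True)
    summaries = summarize_condition(cells_df)
    return (summaries[0] if summaries else None), cells_df
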