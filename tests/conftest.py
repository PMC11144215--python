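"""Shared fixtures: synthetic cohorts and a desk-scale trained model.

The heavy fixtures are session-scoped; the parameter-recovery cohort
(60 slides of 5x5 tiles, 40 train / 20 hold-out, half the tissue tiles
of each positive slide carrying the solid-nest morphology) is generated
once and reused by the MIL and acceptance tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

import histoscreen as hs
from histoscreen.features import HandcraftedBackbone
from histoscreen.mil import bag_from_slide, fit_mil


@pytest.fixture(scope="session")
def backbone():
    return HandcraftedBackbone()


@pytest.fixture(scope="session")
def recovery_cohort(tmp_path_factory, backbone):
    """60-slide labeled cohort with bags, truth maps and a 40/20 split."""
    out = tmp_path_factory.mktemp("cohort")
    template = hs.SyntheticSlideSpec(
        slide_id="template",
        label="negative",
        width_px=1120,
        height_px=1120,
        signal_fraction=0.5,
    )
    manifest = hs.generate_cohort(60, 0.4, template, seed=7, out_dir=out)
    bags, truth = {}, {}
    for row in manifest.itertuples():
        bags[row.slide_id] = bag_from_slide(row.file_path, backbone)
        truth[row.slide_id] = pd.read_csv(row.file_path.replace(".tiff", ".truth.csv"))
    split = hs.stratified_splits(manifest, holdout_fraction=20 / 60, n_folds=5, seed=7)
    return {
        "manifest": manifest,
        "bags": bags,
        "truth": truth,
        "labels": dict(zip(manifest.slide_id, manifest.label)),
        "train_ids": split[split.partition == "train"].slide_id.tolist(),
        "test_ids": split[split.partition == "holdout"].slide_id.tolist(),
    }


@pytest.fixture(scope="session")
def trained_model(recovery_cohort):
    """Attention-MIL model fit on the 40 training slides."""
    c = recovery_cohort
    config = hs.MILConfig(learning_rate=3e-3, epochs=120, dropout=0.5, seed=7)
    model, history = fit_mil(
        [c["bags"][s] for s in c["train_ids"]],
        [c["labels"][s] for s in c["train_ids"]],
        config,
    )
    return model
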