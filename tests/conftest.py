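"""Shared fixtures: a desk-scale single-subject pipeline run.

The expensive stages (EEMD, expMSE) are computed once per session and
shared across the integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from expmse_decode.config import RunConfig
from expmse_decode.decoder import cross_validate, make_intra_folds
from expmse_decode.io_h5 import read_crops
from expmse_decode.pipeline import (stage_decompose, stage_entropy,
                                    stage_features, stage_simulate)

#: Region labels of the reduced cohort, grouped by cortical system.
REDUCED_GROUPS = {
    "occipital": ("lateraloccipital-lh", "pericalcarine-lh"),
    "central": ("precentral-lh", "postcentral-lh"),
    "prefrontal": ("superiorfrontal-lh", "rostralmiddlefrontal-lh"),
}
#: Band injected per task in the strong-effect fixture.
INJECTED = {
    "VP": ("occipital", "gamma"),
    "VI": ("occipital", "alpha"),
    "ME": ("central", "beta"),
    "MI": ("central", "alpha"),
}


@pytest.fixture(scope="session")
def reduced_run(tmp_path_factory):
    """One-subject reduced cohort run through simulate..features."""
    out = tmp_path_factory.mktemp("reduced_run")
    cfg = RunConfig.from_dict({"seed": 1, "simulation": {"n_subjects": 1}})
    paths = stage_simulate(cfg, out)
    stage_decompose(cfg, out, paths)
    stage_entropy(cfg, out, paths)
    stage_features(cfg, out, paths)
    return cfg, paths, out


@pytest.fixture(scope="session")
def expmse_crops(reduced_run):
    cfg, paths, _ = reduced_run
    crop_set = read_crops(paths[0], "expmse")
    crop_set.trial_meta["subject"] = 0
    return crop_set


@pytest.fixture(scope="session")
def signal_decode(reduced_run, expmse_crops):
    """True-label decoding on a 6-fold subset of the intra-subject plan.

    Returns (report, trained models, sub-plan, crop set).  Six of the
    twelve folds keep the compute modest while covering every group as
    both validation and test data at least once.
    """
    from expmse_decode.decoder import FoldPlan
    from expmse_decode.pipeline import _spec

    cfg, _, _ = reduced_run
    plan = make_intra_folds(expmse_crops.trial_meta, seed=cfg.seed)
    sub_plan = FoldPlan(design="intra", folds=plan.folds[::2])
    spec = _spec(cfg, expmse_crops)
    report, models = cross_validate(expmse_crops, sub_plan, spec,
                                    keep_models=True)
    return report, models, sub_plan, expmse_crops


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
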