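"""Shared fixtures: one synthetic study, built once per session.

The expensive stages (rendering the training set, fitting readouts, sampling
selection candidates, simulating observers) are session-scoped so the whole
suite pays for them once.  Problem sizes are reduced relative to the
full-scale defaults (4,000 instead of 10,000 selection iterations, 8 subjects
per species) but kept large enough for the statistical recovery checks
(split-half reliability of the simulated data > 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vistrat import behavior, decoder, selection, stats, stimuli
from vistrat.backbone import SyntheticBackbone

SELECTION_ITERS = 4000
SELECTION_SEED = 7
N_SUBJECTS = 8
N_SESSIONS = 10
SIM_SEED = 9000


@pytest.fixture(scope="session")
def backbone():
    return SyntheticBackbone()


@pytest.fixture(scope="session")
def training_data():
    specs, labels = stimuli.training_stimuli()
    imgs = np.stack([stimuli.render(s).pixels for s in specs])
    return specs, labels, imgs


@pytest.fixture(scope="session")
def ensemble(backbone, training_data):
    _, labels, imgs = training_data
    return decoder.fit_readouts(backbone, imgs, labels, noise=0.0, seed=0)


@pytest.fixture(scope="session")
def calibration(backbone, training_data):
    _, labels, imgs = training_data
    return decoder.calibrate_noise(backbone, imgs, labels, target=0.75,
                                   iters=100, seed=11)


@pytest.fixture(scope="session")
def candidates(ensemble):
    targets, distractors = selection.default_pool()
    cands = selection.sample_candidates(ensemble, targets, distractors,
                                        n_iter=SELECTION_ITERS, seed=SELECTION_SEED)
    cands, early_sd, late_sd = selection.standardize(cands)
    return cands


@pytest.fixture(scope="session")
def informed_protocols(candidates):
    protos = {}
    for profile in ("zero_vs_high", "high_vs_zero"):
        res = selection.filter_select(
            candidates, selection.SelectionCriteria(profile=profile))
        assert not res.underfull
        protos[profile] = selection.build_informed_protocol(res)
    return protos


@pytest.fixture(scope="session")
def all_scores(ensemble, informed_protocols):
    frames = []
    for name in stimuli.TEST_PROTOCOLS:
        proto = informed_protocols.get(name) or stimuli.protocol_pairs(name)
        frames.append(decoder.score_pairs(ensemble, proto, include_old_pair=True))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def score_matrix(all_scores):
    test_scores = all_scores[~all_scores["is_old"]]
    pair_order = list(dict.fromkeys(test_scores["pair_id"]))
    mat = (test_scores.pivot_table(index="pair_id", columns="sublayer",
                                   values="classification_score")
           .reindex(pair_order).to_numpy())
    return pair_order, mat


@pytest.fixture(scope="session")
def sim_trials(all_scores):
    """Trial tables for both species presets over all nine test protocols."""
    sg = stimuli.DEFAULT_SUBGRID
    old_id = decoder.pair_id(sg.base_target, sg.base_distractor)
    rat, human = behavior.species_presets()
    frames = []
    for observer in (rat, human):
        for i in range(N_SUBJECTS):
            for j, name in enumerate(stimuli.TEST_PROTOCOLS):
                sc = all_scores[all_scores["protocol"] == name]
                frames.append(behavior.simulate_sessions(
                    observer, sc, behavior.TEST_SESSION, n_sessions=N_SESSIONS,
                    subject=f"{observer.species}-{i}", seed=SIM_SEED + 137 * i + j,
                    old_pair_id=old_id))
    return pd.concat(frames, ignore_index=True)
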