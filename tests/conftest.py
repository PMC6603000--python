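"""Shared fixtures.

The expensive end-to-end batteries (10 synthetic fields per condition at
256 x 256) are session-scoped and lazily evaluated so the whole-pipeline
checks share one computation; only scalar summaries are retained.
"""

from __future__ import annotations

import numpy as np
import pytest

from rosellapipe import run_autophagy_field, run_mitophagy_field
from rosellapipe.simulate import render_suite

N_FIELDS = 10
BASE_SEED = 1


@pytest.fixture()
def rng():
    return np.random.default_rng(20_210_521)


def _autophagy_battery(config: str, base_seed: int):
    per_field = []
    for stack, truth in render_suite(config, N_FIELDS, base_seed):
        result = run_autophagy_field(stack)
        per_field.append(
            {
                "detected": dict(result.summary.counts),
                "rate": result.summary.autophagy_rate,
                "vacuoles": result.summary.autophagic_vacuoles,
                "truth": truth.objects["object_class"].value_counts().to_dict(),
            }
        )
    return per_field


@pytest.fixture(scope="session")
def small_field():
    """One small rendered field plus its staging result, shared read-only."""
    from rosellapipe.simulate import SceneSpec, render_scene

    spec = SceneSpec(
        shape=(5, 128, 128), seed=42,
        n_phagophore=3, n_autophagosome=1,
        n_early_autolysosome=1, n_late_autolysosome=3,
    )
    stack, truth = render_scene(spec)
    result = run_autophagy_field(stack)
    return stack, truth, result


@pytest.fixture(scope="session")
def basal_battery():
    """Detected vs ground-truth class counts on 10 basal fields."""
    return _autophagy_battery("basal", BASE_SEED)


@pytest.fixture(scope="session")
def chloroquine_battery():
    return _autophagy_battery("chloroquine-like", BASE_SEED + 300)


def _mito_battery(config: str, base_seed: int):
    per_field = []
    for stack, truth in render_suite(config, N_FIELDS, base_seed):
        result = run_mitophagy_field(stack)
        gt_mask = truth.labels["mitochondria"] > 0
        detected = np.asarray(result.masks.mito_mask, dtype=bool)
        per_field.append(
            {
                "events": result.summary.mitophagy_event_count,
                "events_truth": truth.count("mitophagy_event"),
                "tubule_recall": float((detected & gt_mask).sum() / gt_mask.sum()),
                "mito_volume_um3": result.summary.mito_volume_um3,
            }
        )
    return per_field


@pytest.fixture(scope="session")
def basal_mito_battery():
    return _mito_battery("basal-mito", BASE_SEED + 600)


@pytest.fixture(scope="session")
def cccp_battery():
    return _mito_battery("cccp-like", BASE_SEED + 600)
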