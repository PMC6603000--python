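"""Report the margin of each rendered class signature against the pipeline's
graytone decision points.

The simulator's intensity defaults are a fixed calibration: each vesicle
class must sit on the correct side of the pipeline's decision thresholds (band-pass
> 400, top-hat > 1200, green band-pass > 1000, Butterworth mask > 150,
ratio rules at 2 and 0.6, ...) at the reference signal-to-background.  This
script renders one basal field per reporter and prints, for every decision
point, the relevant response inside the rendered objects versus in the
background, so the margins can be inspected after any change to the
generator or the optics model.

    python scripts/calibration.py [--seed 1]
"""

from __future__ import annotations

import argparse
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from rosellapipe import PipelineConfig, run_autophagy_field, run_mitophagy_field  # noqa: E402
from rosellapipe.filters import GaussianSpec, butterworth_highpass, difference_of_gaussians  # noqa: E402
from rosellapipe.simulate import render_suite  # noqa: E402


def q(x, p):
    return float(np.percentile(x, p))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = PipelineConfig()

    (stack, truth), = render_suite("basal", 1, args.seed)
    result = run_autophagy_field(stack)
    masks = result.masks
    bg = np.ones(stack.green.shape, dtype=bool)
    for labels in truth.labels.values():
        bg &= labels == 0

    print("== Rosella-LC3 basal field ==")
    red_dog = difference_of_gaussians(
        np.asarray(stack.red, float), GaussianSpec(*cfg.dsred_dog_fg),
        GaussianSpec(*cfg.dsred_dog_bg))
    late = truth.labels["late_autolysosome"] > 0
    print(f"red band-pass > {cfg.dsred_dog_threshold:.0f}: "
          f"late-autolysosome p50 {q(red_dog[late], 50):.0f}, "
          f"background p99.9 {q(red_dog[bg], 99.9):.0f}")
    ftb = butterworth_highpass(masks.green_dog, cfg.butterworth_cutoff,
                               cfg.butterworth_order)
    ring = truth.labels["autophagosome"] > 0
    print(f"Butterworth mask > {cfg.euler_threshold:.0f}: "
          f"ring-rim p75 {q(ftb[ring], 75):.0f}, "
          f"background p99.9 {q(ftb[bg], 99.9):.0f}")
    ratio = result.ratio
    ph = truth.labels["phagophore"] > 0
    ea = truth.labels["early_autolysosome"] > 0
    print(f"median ratio rule at {cfg.phagophore_median_ratio}: "
          f"phagophore p50 {q(ratio[ph], 50):.2f}, "
          f"early p50 {q(ratio[ea], 50):.2f}, late p50 {q(ratio[late], 50):.2f}")
    print(f"detected counts: {result.summary.counts}")

    (stack, truth), = render_suite("basal-mito", 1, args.seed)
    result = run_mitophagy_field(stack)
    print("\n== ATP5C1-Rosella basal field ==")
    tub = truth.labels["mitochondria"] > 0
    ev = truth.labels["mitophagy_event"] > 0
    mito_dog = result.masks.mito_dog
    print(f"mito band-pass > {cfg.mito_threshold:.0f}: "
          f"tubule p50 {q(mito_dog[tub], 50):.0f}")
    ratio = result.ratio
    print(f"seed ratio rule at {cfg.mitophagy_ratio_threshold}: "
          f"tubule p50 {q(ratio[tub], 50):.2f}, event p50 {q(ratio[ev], 50):.2f}")
    print(f"events detected: {result.summary.mitophagy_event_count} "
          f"of {truth.count('mitophagy_event')} rendered")


if __name__ == "__main__":
    main()
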