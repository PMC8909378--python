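"""Desk-scale reference experiments.

The full clinical-scale workflow (hundreds of 512-voxel scans, GPU
training) does not fit an interactive development loop, so the package
ships one frozen desk-scale experiment exercising every pipeline stage
end to end on phantom data: generate a small resolution-heterogeneous
cohort, preprocess with the 1% slice filter, train the six-member
loss-diverse ensemble, fuse by logit summation, and score held-out
patients with pooled global Dice.

Problem sizes are fixed here as the package's reference configuration:
8 patients x 5 time points on 48 x 64 x 96 grids (6 patients train,
2 held out), a (64, 96) network input — the phantom lung bounding box
fits it at native resolution, so no slice is downscaled — base filters
4 and 8, and 200 Adam steps per member. One integer seed determines the
cohort, member initialisations and shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as ev
from . import phantom, preprocess, segnet

__all__ = ["RecoveryResult", "scaled_down_recovery"]

INPUT_SHAPE = (64, 96)
FILTERS = (4, 8)
HYPER = segnet.Hyper(epochs=4, batch_size=2, lr=3e-3, max_steps=200)


@dataclass
class RecoveryResult:
    """Held-out evaluation of the scaled-down stage-two ensemble."""

    report: ev.EvalReport
    frequencies_all: preprocess.ClassFrequencies
    frequencies_filtered: preprocess.ClassFrequencies
    n_train_slices: int
    n_test_scans: int


def scaled_down_recovery(
    seed: int,
    n_train_patients: int = 6,
    n_test_patients: int = 2,
    cases: list | None = None,
) -> RecoveryResult:
    """Run the frozen end-to-end recovery experiment for one seed.

    ``cases`` may supply a pre-generated cohort (seeded elsewhere) to
    amortise generation across repeated runs; it must contain
    ``n_train_patients + n_test_patients`` patients. Training uses the
    filtered slices of the first ``n_train_patients`` patients; global
    Dice is pooled over every scan of the remaining held-out patients.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seed, train_seed = (int(s) % 2 ** 31 for s in ss.generate_state(2))
    if cases is None:
        spec = phantom.PhantomSpec(
            n_patients=n_train_patients + n_test_patients, seed=cohort_seed
        )
        cases, _ = phantom.generate_cohort(spec)
    patients = list(dict.fromkeys(c.patient_id for c in cases))
    if len(patients) != n_train_patients + n_test_patients:
        raise ValueError("cohort does not match the requested patient counts")
    train_ids = set(patients[:n_train_patients])
    train_cases = [c for c in cases if c.patient_id in train_ids]
    test_cases = [c for c in cases if c.patient_id not in train_ids]

    plans = {id(c): preprocess.plan_case(c, target=INPUT_SHAPE) for c in cases}
    samples = []
    for c in train_cases:
        samples.extend(preprocess.make_samples(c, plans[id(c)]))

    config = segnet.stage_two_preset(
        input_shape=INPUT_SHAPE, filters=FILTERS, seed=train_seed
    )
    rng = np.random.default_rng(train_seed)
    models = [
        segnet.train(m, samples, HYPER, seed=int(rng.integers(2 ** 31)))[0]
        for m in config.members
    ]
    preds = [segnet.predict_case(models, c, plans[id(c)]) for c in test_cases]
    report = ev.evaluate_set(
        preds,
        [c.labels for c in test_cases],
        [c.lung_mask.bool for c in test_cases],
        scan_set="held-out",
    )
    return RecoveryResult(
        report=report,
        frequencies_all=preprocess.class_frequencies(train_cases, "all"),
        frequencies_filtered=preprocess.class_frequencies(train_cases, "filtered"),
        n_train_slices=len(samples),
        n_test_scans=len(test_cases),
    )
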