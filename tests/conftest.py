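import numpy as np
import pytest

from seltrack import synth, tracking


@pytest.fixture(scope="session")
def one_subject_trials():
    """12 simulated trials (12 s) for one subject, spanning the SNR grid."""
    truth = synth.make_ground_truth(["S01"], seed=11)
    rng = np.random.default_rng(21)
    triples = synth.enumerate_conditions()
    snrs = np.linspace(-12, 4, 12)
    designs = [
        synth.TrialDesign(
            f"S01_T{k:02d}", "S01", *triples[k % 16], snr_db=float(s), duration_s=12.0
        )
        for k, s in enumerate(snrs)
    ]
    seeds = rng.integers(2**31, size=len(designs))
    trials = [synth.simulate_trial(d, truth, int(s)) for d, s in zip(designs, seeds)]
    return trials, truth


@pytest.fixture(scope="session")
def one_subject_scores(one_subject_trials):
    trials, truth = one_subject_trials
    return tracking.crossval_scores(trials), trials, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 16 short trials: shared by io/pipeline/validate tests."""
    config = synth.ExperimentConfig(
        n_subjects=2, n_trials_per_subject=16, duration_s=10.0,
        recall_snr_levels=12, recall_words_per_level=40,
    )
    return synth.simulate_experiment(config, seed=5), config
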