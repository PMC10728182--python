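"""Shared fixtures: tiny hand-built datasets and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from semforage import coding, fluency_io, preprocess, synthetic


class IdentityRng:
    """Stands in for a Generator but applies the identity permutation."""

    def permutation(self, x):
        return np.asarray(x).copy()


@pytest.fixture
def small_lexicon() -> fluency_io.Lexicon:
    return fluency_io.lexicon_from_pairs(
        [
            ("Canine", "dog"), ("Canine", "fox"), ("Canine", "wolf"),
            ("Pets", "dog"), ("Pets", "cat"),
            ("Aquatic", "whale"), ("Aquatic", "fish"), ("Aquatic", "shark"),
            ("African", "giraffe"), ("African", "lion"), ("African", "zebra"),
        ]
    )


def build_dataset(
    lists: list[tuple[str, int, list[tuple[str, float]]]],
    lexicon: fluency_io.Lexicon,
) -> coding.CodedDataset:
    """Build a coded dataset from (participant, trial, [(item, rt_ms), ...])."""
    rows = []
    for pid, trial, items in lists:
        for pos, (item, rt) in enumerate(items, start=1):
            rows.append({"participant": pid, "trial": trial, "position": pos,
                         "item": item, "rt_ms": rt})
    frame = pd.DataFrame(rows)
    fls = fluency_io.fluency_lists_from_frame(frame)
    return coding.code_dataset(fls, lexicon)


@pytest.fixture
def dataset_builder():
    return build_dataset


def simulate_retained(config: synthetic.GeneratorConfig):
    """Simulate a cohort and push it through coding + exclusions."""
    study = synthetic.simulate_dataset(config)
    fls = fluency_io.fluency_lists_from_frame(study.responses)
    coded = coding.code_dataset(fls, study.lexicon)
    retained, report = preprocess.apply_exclusions(coded)
    return study, retained, report


@pytest.fixture(scope="session")
def optimal_cohort():
    """200 MVT-optimal synthetic participants, fully preprocessed."""
    config = synthetic.GeneratorConfig(n_participants=200, seed=11)
    return simulate_retained(config)
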