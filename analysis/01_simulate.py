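#!/usr/bin/env python
"""Simulate the study cohort.

Generates a synthetic animal-fluency cohort under the default study
conditions (527 participants, three 3-minute trials each, MVT-optimal
patch-leaving) and writes the canonical fluency CSV, the generating
lexicon, and the ground-truth JSON under results/simulated/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from semforage.synthetic import GeneratorConfig, simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 1


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    study = simulate_dataset(config)
    study.write(OUT)
    per_list = study.responses.groupby(["participant", "trial"]).size()
    print(f"simulated {config.n_participants} participants, "
          f"{len(per_list)} lists, {len(study.responses)} responses "
          f"(mean {per_list.mean():.1f}/list)")
    print(f"ground truth: optimal leave count "
          f"{study.ground_truth['optimal_leave_count']}, residence "
          f"{study.ground_truth['optimal_leave_time_ms']:.0f} ms, global rate "
          f"{study.ground_truth['optimal_rate_per_ms']:.3g}/ms")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
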