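#!/usr/bin/env python
"""Code the cohort into clusters and apply the exclusion rules.

Reads results/simulated/, assigns categories with the fluid switch rule,
applies the list/participant exclusion criteria, and writes the coded
table plus the exclusion audit under results/coded/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from semforage import coding, fluency_io, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lists, read_report = fluency_io.read_fluency_table(ROOT / "simulated" / "fluency.csv")
    lexicon = fluency_io.read_lexicon(ROOT / "simulated" / "lexicon.csv")
    coded = coding.code_dataset(lists, lexicon)
    retained, report = preprocess.apply_exclusions(coded)

    out = ROOT / "coded"
    fluency_io.write_results(
        {"coded_responses": coding.coded_frame(retained),
         "exclusions": report.to_frame()},
        out,
    )
    print(f"read {read_report.rows_read} rows -> {read_report.lists_formed} lists")
    print(f"retained {report.n_participants_retained}/{report.n_participants_in} "
          f"participants ({report.n_lists_retained} lists)")
    n_clusters = coding.coded_frame(retained)["cluster_id"].nunique()
    print(f"{n_clusters} clusters identified")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
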