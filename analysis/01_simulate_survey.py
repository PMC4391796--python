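#!/usr/bin/env python
"""Generate the survey-shaped two-marker dataset used by the other steps.

Writes aligned COI and ITS2 FASTA, the specimen metadata table and the
true lineage assignment under results/survey_data/.
"""

import argparse
from pathlib import Path

from barcodegap.cli import run_simulate
from barcodegap.synthetic import survey_config

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results/survey_data")
    args = ap.parse_args()
    paths = run_simulate(survey_config(args.seed), args.out)
    for key, p in paths.items():
        print(f"{key}: {p}")


if __name__ == "__main__":
    main()
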