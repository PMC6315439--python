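"""Generate a synthetic two-disease multi-study dataset with known truth.

Writes per-study differential tables (obfuscated accessions), study metadata,
the identifier map and the planted truth under results/sim/. Downstream
scripts consume these files, so the whole pipeline is exercised end to end
from flat files.
"""

import argparse
from pathlib import Path

from prometa import default_two_disease_config, simulate_study_set, write_study_set

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = default_two_disease_config(seed=args.seed)
    studies, idmap, truth = simulate_study_set(config)
    out_dir = RESULTS / "sim"
    write_study_set(studies, idmap, truth, out_dir)

    n_records = sum(len(t) for t in studies)
    print(f"simulated {len(studies)} studies ({n_records} records) over "
          f"{config.n_genes} genes; planted "
          f"{len(truth['planted']['ALS'])} ALS / {len(truth['planted']['SMA'])} SMA genes, "
          f"{len(truth['shared_symbols'])} shared")
    print(f"files written under {out_dir}")


if __name__ == "__main__":
    main()
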