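"""Simulate the two-state co-fractionation study with planted ground truth.

Generates the default study design — 50 planted complexes (2-10 members),
200 background proteins, 20% of complexes rewired between the stem-cell-like
(ECSC) and neuronal-like (DNLC) states — and the full 2 x SEC/IEC x
duplicate-replicate set of elution matrices.  Matrices and truth files go to
scratch/study/ (inputs for the later steps); a small design summary goes to
results/.
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

from cofracnet import pipeline as pl
from cofracnet.io import write_complex_catalog, write_experiment
from cofracnet.simulate import STATES, simulate_all_experiments

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SCRATCH = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    truth = pl.default_truth(seed=SEED)
    experiments = simulate_all_experiments(truth)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    for exp in experiments:
        write_experiment(exp, SCRATCH / f"{exp.state}_{exp.technique}_{exp.replicate}.tsv")
    for state in STATES:
        write_complex_catalog(truth.catalog(state), SCRATCH / f"truth_{state}.gmt")
    with (SCRATCH / "truth_rewired_pairs.tsv").open("w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(truth.rewired_pairs):
            fh.write(f"{a}\t{b}\n")

    sizes = Counter(len(m) for m in truth.complexes_per_state[STATES[0]])
    summary = pd.DataFrame(
        {
            "quantity": ["proteins", "complexes", "background_proteins",
                         "rewired_pairs", "experiments"]
            + [f"complexes_of_size_{s}" for s in sorted(sizes)],
            "value": [
                len(truth.protein_universe),
                len(truth.complexes_per_state[STATES[0]]),
                len(truth.protein_universe) - len(truth.complex_members(STATES[0])),
                len(truth.rewired_pairs),
                len(experiments),
            ]
            + [sizes[s] for s in sorted(sizes)],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_study_design.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote {len(experiments)} elution matrices to {SCRATCH}/")


if __name__ == "__main__":
    main()
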