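#!/usr/bin/env python
"""Simulate sequence-agnostic model-building output across resolutions.

Generates the study's synthetic reference protein, draws a fragment set at
the near-atomic working resolution (2.5 Å-equivalent), and tabulates how the
residue share of short/medium/long chains shifts as nominal resolution
degrades — the sequence-space analogue of binning built chains by length.

Writes: results/reference.fasta, results/fragments_2.5A.fasta,
results/chain_length_profile.csv
"""

from pathlib import Path

import pandas as pd

from fragid import fragsim, io

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 11
REFERENCE_LENGTH = 234  # resolved E2 catalytic-domain segment
COVERAGE_MULTIPLE = 3.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    reference = fragsim.synthetic_reference(REFERENCE_LENGTH, seed=SEED)
    io.write_fasta(
        [("reference", fragsim.TARGET_DESCRIPTION + " (synthetic)", reference)],
        OUT / "reference.fasta",
    )

    params = fragsim.degradation_from_resolution(2.5)
    n = round(COVERAGE_MULTIPLE * len(reference) / params.mean_fragment_length)
    fragset = fragsim.simulate_fragments(reference, params, n, seed=SEED)
    io.write_fragments_fasta(fragset, OUT / "fragments_2.5A.fasta")
    print(
        f"2.5 Å-equivalent: {len(fragset)} fragments, "
        f"mean length {fragset.total_residues / len(fragset):.1f} residues, "
        f"substitution error rate {params.substitution_error_rate:.2f}"
    )

    rows = []
    for res in (2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0):
        p = fragsim.degradation_from_resolution(res)
        n = round(COVERAGE_MULTIPLE * len(reference) / p.mean_fragment_length)
        fs = fragsim.simulate_fragments(reference, p, n, seed=SEED)
        frac = fragsim.chain_length_profile(fs)
        rows.append(
            {
                "resolution": res,
                "mean_length_param": p.mean_fragment_length,
                "n_fragments": len(fs),
                "frac_1_10": round(frac[0], 4),
                "frac_11_100": round(frac[1], 4),
                "frac_gt_100": round(frac[2], 4),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "chain_length_profile.csv", index=False)
    print("\nResidue share per chain-length bin vs nominal resolution:")
    print(df.to_string(index=False))
    print(
        "\nFinding: the residue share of >100-residue chains collapses as "
        "resolution degrades, while 1-10-residue stubs take over - the "
        "expected signature of model building on worsening maps."
    )


if __name__ == "__main__":
    main()
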