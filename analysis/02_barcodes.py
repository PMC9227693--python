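#!/usr/bin/env python
"""Construct the tumor barcodes and compare Bayesian vs sign-test detection.

From the tallied library of 01_build_library.py: metabolites at frequency
>= 3 whose signed Bayes factor exceeds 3 in magnitude form the barcode of
each sample type; the same tallies are scored by the one-sided exact sign
test for the method comparison.
"""

from pathlib import Path

from metabarcode.library import filter_by_frequency, load_library, tally_votes
from metabarcode.votecount import barcode_to_frame, build_barcode, compare_methods

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = load_library(RESULTS / "library.tsv")
    for sample_type in ("blood", "tissue"):
        kept = filter_by_frequency(tally_votes(records, sample_type), 3)
        barcode = build_barcode(kept)
        barcode_to_frame(barcode).to_csv(
            RESULTS / f"barcode_{sample_type}.tsv", sep="\t", index=False
        )
        comparison = compare_methods(kept)
        comparison.to_csv(
            RESULTS / f"method_comparison_{sample_type}.tsv", sep="\t", index=False
        )
        up = sum(1 for e in barcode if e.direction > 0)
        down = sum(1 for e in barcode if e.direction < 0)
        print(
            f"{sample_type}: barcode {len(barcode)} entries ({up} up, {down} down); "
            f"detected by Bayes factor: {comparison.attrs['n_detected_bayes']}, "
            f"by sign test: {comparison.attrs['n_detected_sign']}"
        )


if __name__ == "__main__":
    main()
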