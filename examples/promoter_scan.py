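"""Scan a promoter window upstream of a TSS for estrogen-response-like sites.

Builds a toy estrogen-receptor-style position weight matrix (an ERE-like
palindromic preference), plants its consensus 725 bp upstream of the TSS of
a random 5 kb promoter, and scans both strands at a 75% minimal matching
score — the same reporting convention (percent of the min-max score range,
bp upstream of the TSS) used for real promoter searches.
"""

import numpy as np

from pitsync import PWM, PromoterSequence, scan_promoter

# ERE-like half sites AGGTCA ... TGACCT with a weak 3-bp spacer
COUNTS = {
    "A": [85, 2, 2, 2, 2, 85, 25, 25, 25, 2, 2, 85, 2, 2, 2],
    "C": [5, 2, 2, 2, 85, 5, 25, 25, 25, 2, 2, 5, 85, 85, 2],
    "G": [5, 85, 85, 2, 2, 5, 25, 25, 25, 2, 85, 5, 2, 2, 2],
    "T": [5, 11, 11, 94, 11, 5, 25, 25, 25, 94, 11, 5, 11, 11, 94],
}


def main() -> None:
    pwm = PWM("ERE-like", np.array([COUNTS[b] for b in "ACGT"], dtype=float))
    rng = np.random.default_rng(6)
    window = 5000
    seq = "".join(rng.choice(list("ACGT"), window))
    start = window - 725 - len(pwm) + 1
    seq = seq[:start] + pwm.consensus + seq[start + len(pwm) :]
    promoter = PromoterSequence(seq, tss_index=window, window_length=window)

    hits = scan_promoter(pwm, promoter, min_score=75.0)
    print(f"consensus: {pwm.consensus}")
    print(f"{len(hits)} hit(s) at >=75% minimal matching score in 5 kb:")
    for h in hits:
        print(
            f"  {h.strand} strand, {h.bp_upstream:>4} bp upstream of TSS, "
            f"{h.relative_score:5.1f}% ({h.sequence})"
        )
    print(
        "\nScores are min-max-normalized log-odds: the consensus scores 100%, "
        "the worst possible site 0%."
    )


if __name__ == "__main__":
    main()
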