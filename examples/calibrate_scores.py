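"""Percentile-rank and Phred calibration of raw classifier scores.

Raw scores only mean something relative to the genome-wide score population,
so they are converted to percentile ranks and then Phred-scaled with
f(x) = -10 log10(1 - x).  A variant scoring higher than 95% of the genome
gets Phred 13.01; higher than 99% gets 20.  The transform is monotone, so a
"top 5% of the genome" rule is the same classification on any scale.
"""

import numpy as np

import mpradesign as m

rng = np.random.default_rng(3)
reference = m.CalibrationReference(rng.beta(2, 8, size=100_000))  # genome-wide stand-in

for raw in (0.05, 0.2, 0.5, 0.8):
    rank = m.percentile_rank(raw, reference)
    print(f"raw {raw:.2f} -> percentile rank {rank:.4f} -> Phred {m.phred(rank, reference.n):6.2f}")

print(f"\nPhred at rank 0.95 (genome-wide positive cutoff): {m.phred(0.95):.4f}")
budget = m.fraction_for_count(100_000, 9_200_000)
thr = m.threshold_for_fraction(reference, budget)
print(f"assaying 100,000 of 9.2M candidates = top fraction {budget}")
print(f"corresponding raw-score threshold: {thr:.4f} "
      f"({int((reference.scores >= thr).sum())} reference variants selected)")
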