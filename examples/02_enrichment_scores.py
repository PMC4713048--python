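"""Weighted-KS enrichment of a probe set in a ranked response pattern.

Walks a small ranked list with the running hit/miss sum and shows how
a set concentrated at the top scores near +1, at the bottom near -1,
and scattered sets score near 0.
"""

import numpy as np

from mirconnect import RankedResponsePattern, enrichment_score

rng = np.random.default_rng(0)
stats = np.sort(rng.normal(size=20))[::-1]
pattern = RankedResponsePattern([f"g{i:02d}" for i in range(20)], stats)

top = set(pattern.probe_ids[:4])
bottom = set(pattern.probe_ids[-4:])
scattered = set(pattern.probe_ids[2::5])

for name, probe_set in [("top-4", top), ("bottom-4", bottom),
                        ("scattered", scattered)]:
    res = enrichment_score(probe_set, pattern, p=1.0)
    print(f"{name:9s} ES={res.es:+.3f} at position {res.arg_position}")

# the full running sum is available for diagnostics
res = enrichment_score(top, pattern, keep_running_sum=True)
print("running sum (top-4):",
      np.array2string(res.running_sum[:8], precision=2))
# ES is the signed extreme of this walk; +1/-1 mean the whole set sits
# above/below every non-member.
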