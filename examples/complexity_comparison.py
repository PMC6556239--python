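"""Compare the computational cost of the two artifact cancellers.

Both filters count their true multiply operations at run time; the
sign-sign canceller needs at most M per sample (three in this
implementation, one per active axis) while NLMS needs 3M + 1.
"""

import numpy as np

from pulsetrack import (NLMSFilter, SignSignFilter,
                        count_weight_multiplications)

M, n = 21, 1000
rng = np.random.default_rng(0)
ss = SignSignFilter(taps=M)
nlms = NLMSFilter(taps=M)
for _ in range(n):
    ss.step(*rng.normal(size=4))
    nlms.step(rng.normal(), rng.normal())

bound_ss, bound_nlms = count_weight_multiplications(M)
print(f"filter order M = {M}")
print(f"sign-sign: {ss.multiplications / n:.0f} multiplies/sample "
      f"(analytic bound {bound_ss})")
print(f"NLMS:      {nlms.multiplications / n:.0f} multiplies/sample "
      f"(analytic count {bound_nlms})")
print("\nThe sign-sign canceller replaces the inner products of NLMS with")
print("sign-gated additions, which is what makes it attractive for")
print("wearable hardware without a floating-point unit.")
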