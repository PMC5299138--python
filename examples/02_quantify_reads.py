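"""Small-RNA read quantification on simulated reads.

Simulates adapter-ligated 50 bp reads from a two-miRNA expression
profile, then runs the quantifier (adapter trim -> quality/length
filter -> exact match to mature sequences -> RPM) and compares the
recovered RPM proportions with the simulated ones.
"""

import numpy as np

from mirshift.io_formats import MirnaExpressionProfile
from mirshift.quant import QuantConfig, quantify, rpm_normalize
from mirshift.synthetic_data import (
    SyntheticConfig,
    generate_mature_reference,
    generate_reads,
)

rng = np.random.default_rng(7)
reference = generate_mature_reference(["mir-red", "mir-blue"], rng)
profile = MirnaExpressionProfile(
    ("E60", "E80"), {"mir-red": (0.0, 750_000.0), "mir-blue": (0.0, 250_000.0)}
)
config = SyntheticConfig(n_reads=50_000, read_error_rate=0.005, seed=7)
reads = generate_reads(profile, reference, config, timepoint="late", rng=rng)

result = quantify(reads, reference, QuantConfig(adapter=config.adapter))
rpm = rpm_normalize(result.counts, result.mapped_total)

print(f"reads simulated: {result.n_input}")
print(f"pass trim+filter: {result.n_pass_filter}  mapped: {result.mapped_total}")
print("(unmapped reads carry simulated sequencing errors; exact matching drops them)")
for mirna in reference.entries:
    print(f"  {mirna:<9} count {result.counts[mirna]:>6}  RPM {rpm[mirna]:>9.1f}")
print(
    "RPM proportions track the simulated 75/25 split; the RPM column "
    f"sums to {sum(rpm.values()):.0f} by construction."
)
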