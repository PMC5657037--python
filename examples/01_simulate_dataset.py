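"""Generate a synthetic paired-platform dataset and look at what it contains.

The generator spikes 700 somatic SNVs (100 per exome-depth stratum plus
100 covered only by the genome), 500 germline heterozygous sites and
1000 background noise sites onto one synthetic contig, then runs the two
emulated callers on both platforms and writes their native output files.
"""

import tempfile
from pathlib import Path

from snvensemble import SimConfig, generate_dataset

out_dir = Path(tempfile.mkdtemp()) / "dataset"
cfg = SimConfig(seed=1)
files = generate_dataset(cfg, out_dir)

print(f"dataset written to {out_dir}:")
for name, path in files.items():
    n_rows = sum(1 for line in open(path) if not line.startswith("#"))
    print(f"  {name:12s} {path.name:28s} {n_rows:6d} data rows")

# The truth VCF holds the 700 spiked variants (the positives); the two
# call_stats tables hold every candidate the conservative caller examined
# with its KEEP/REJECT verdict; the VCMM tables hold the liberal caller's
# calls, which include most germline sites because it never sees the normal.
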