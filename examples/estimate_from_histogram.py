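"""Estimate genome size from a k-mer histogram file.

Builds a tiny two-peak histogram (the kind `jellyfish histo` would emit for a
heterozygous diploid), runs the estimator, and prints the size report.
"""

import tempfile
from pathlib import Path

import numpy as np

from polykmer import KmerHistogram, estimate_genome_size, read_histogram, write_histogram

# A diploid spectrum in its simplest possible form: 4e5 distinct k-mers unique
# to one homolog at coverage 25 (= C_het), 8e5 shared by both at coverage 50.
hist = KmerHistogram(coverages=np.array([25, 50]), frequencies=np.array([4e5, 8e5]))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "diploid.histo"
    write_histogram(hist, path)          # the on-disk two-column format
    hist = read_histogram(path)          # and back, as a user would load it

report = estimate_genome_size(hist, p=2, C=60)

print(f"C_het (per-haplotype coverage): {report.c_het:.2f}")
for comp, g in zip(report.components, report.region_sizes):
    print(f"  regions on {comp.index} homolog(s): {g:,.0f} bases")
print(f"  repeats: {report.repeat_size:,.0f} bases")
print(f"average haploid genome size G = {report.genome_size:,.0f} bases")
print(f"full genome size G*p          = {report.full_size:,.0f} bases")

# Reading the numbers: the 4e5 heterozygous k-mers cover 4e5 bases on 1 of the
# 2 homologs (2e5 bases of the haploid average); the 8e5 homozygous k-mers
# cover 8e5 on both (8e5 of the average); G = 1.0 Mb, full size 2.0 Mb.
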