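"""End to end: simulated polyploid reads -> k-mer spectrum -> size report.

Simulates a small tetraploid sequencing experiment (diverged homologs,
error-bearing reads), counts canonical k-mers exactly, estimates the genome
size, and writes the report plus a spectrum figure.
"""

import tempfile
from pathlib import Path

from polykmer import (
    estimate_genome_size,
    render_plot,
    simulate_polyploid_reads,
    write_report,
)

hist, truth = simulate_polyploid_reads(
    haploid_len=100_000,   # bases per haplotype
    p=4,                   # tetraploid
    divergence=0.02,       # 2% substitutions between homologs
    depth=30,              # per-haplotype read depth
    read_len=100,
    error_rate=0.005,
    k=17,
    seed=5,
)
print(f"true haploid size 100,000 bases; true C_het {truth.true_c_het:.1f}")

report = estimate_genome_size(hist, p=4, C=2.5 * truth.true_c_het)
print(f"estimated G     {report.genome_size:,.0f} bases "
      f"({100 * (report.genome_size / 100_000 - 1):+.1f}%)")
print(f"estimated C_het {report.c_het:.2f} "
      f"(error k-mers shave it below the error-free value)")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_report(report, {"tsv", "json"}, tmp)
    fig = render_plot(hist, report, path=Path(tmp) / "spectrum.png")
    print("wrote:", ", ".join(sorted(Path(p).name for p in [*paths.values(), fig])))

# The divergence splits k-mers into sharing classes (peaks at 1..4 * C_het);
# the estimator reassembles them into one haploid size. Read errors produce
# the low-coverage spike, which the error cutoff removes before fitting.
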