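"""Chain single-file filters over a simulated exome and watch the counts.

Call quality (> 20, strict), read depth (>= 10), rarity (< 1% population
frequency): each filter is a contraction and their order does not change
the final set.
"""

import tempfile

from varkin import (
    AlleleFrequencyTable,
    filter_aaf,
    filter_call_quality,
    filter_read_depth,
    read_vcf,
)
from varkin.simulate import SimulationSpec, generate_universe, simulate_family

with tempfile.TemporaryDirectory() as tmp:
    spec = SimulationSpec(seed=4, model="AD", n_background_variants=500)
    universe = generate_universe(spec, tmp)
    vcfs, ped, truth = simulate_family(spec, universe, tmp)

    _, variants = read_vcf(vcfs[2])  # the affected child
    table = AlleleFrequencyTable(universe.af_path)
    print(f"input variants:              {len(variants)}")

    step1 = filter_call_quality(variants, 20)
    print(f"after call quality > 20:     {len(step1)}")

    step2 = filter_read_depth(step1, 10)
    print(f"after read depth >= 10:      {len(step2)}")

    step3 = filter_aaf(step2, table, 0.01)
    print(f"after allele frequency < 1%: {len(step3)}")

    planted = {(k[0], k[1]) for k in truth.keys}
    survivors = {(v.chrom, v.pos) for v in step3}
    print(f"planted causal variant retained: {planted <= survivors}")

# Background variants are common (5-45% population frequency), so the
# rarity screen removes essentially all of them while the planted variant,
# absent from the frequency table, passes as novel.
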