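"""The mosaic allele-fraction window.

A post-zygotic mutation is present in only a fraction of cells, so its
alternate-allele read fraction sits well below the ~50% of an ordinary
heterozygote.  The mosaic filter keeps variants whose fraction falls in a
closed window (default 10-35%) in at least one affected sample.
"""

from varkin import MosaicWindow, SampleCall, Variant, filter_mosaic

window = MosaicWindow()  # 0.10 - 0.35, inclusive
print(f"window: [{window.min_af}, {window.max_af}]")

depth = 20
for fraction in (0.05, 0.10, 0.20, 0.35, 0.50):
    alt = round(depth * fraction)
    v = Variant("1", 100, None, "A", ["G"], 50.0, "PASS", {},
                ["GT", "AD", "DP"],
                {"child": SampleCall({"GT": "0/1", "AD": f"{depth-alt},{alt}",
                                      "DP": str(depth)})})
    kept = filter_mosaic([v], window) == [v]
    print(f"alt fraction {fraction:.2f} ({alt}/{depth} reads): "
          f"{'kept (candidate mosaic)' if kept else 'dropped'}")

# 0.05 is indistinguishable from noise / homozygous reference, 0.50 is an
# ordinary germline heterozygote; only the sub-heterozygous band survives.
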