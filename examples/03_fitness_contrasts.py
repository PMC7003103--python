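"""Estimate a strain's competitive fitness from simulated counts.

One strain carries a selection coefficient of s = 0.1 log2 units per
generation in the treatment condition.  Over the ~16 generations between
the T1 and T3 sampling points the difference-in-differences contrast
((T3 trt - T1 trt) - (T3 ctl - T1 ctl)) should estimate s * 16 = 1.6.
"""

import barseqfit as bf

lib = bf.make_barcode_library(40, seed=30)
strains = bf.make_strain_pool(lib, bias_fold_range=22.0, seed=31)
fm = bf.FitnessMap.neutral(lib.strain_ids, ["control", "treatment"])
fm.table.loc["S001", "treatment"] = 0.1

exp = bf.simulate_experiment(
    bf.SerialBatchDesign(seed=32, depth=30_000),
    strains=strains, fitness=fm, library=lib,
)
res = bf.fit_fitness(exp.counts, exp.sample_sheet, reference="control")

row = res.table.set_index(["strain_id", "contrast"]).loc[
    ("S001", "treatment-vs-control")
]
print(f"carrier strain S001: logFC = {row['logFC']:.2f} "
      f"(expected ~1.6), FDR = {row['FDR']:.2e}")
others = res.table[
    (res.table.contrast == "treatment-vs-control")
    & (res.table.strain_id != "S001")
]
print(f"neutral strains: mean logFC = {others['logFC'].mean():+.3f}, "
      f"{int((others['FDR'] < 0.05).sum())}/{len(others)} called significant")
print("(logFC is the log2 fold-change of relative abundance in the treatment "
      "relative to its change in the reference condition)")
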