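"""Stratified subsampling schedule for label-efficiency experiments.

Shows the number of labeled target-domain training measurements retained at
each subsampling ratio for the two target designs (288 and 384 training
samples).  Totals use round-half-up of ratio x n with a largest-remainder
per-class allocation, so classes stay balanced within one sample.
"""

from enoseda import SplitSpec, day_wise_split, generate_domain, stratified_subsample
from enoseda.simdata import target1_preset, target2_preset

split = SplitSpec(set(range(1, 9)), {9, 10})
for name, preset in (("6-class target", target1_preset),
                     ("8-class target", target2_preset)):
    ds = generate_domain(preset(seed=0), domain_tag="target")
    train, test = day_wise_split(ds, split)
    print(f"{name}: {len(train)} train / {len(test)} test")
    for ratio in (1.0, 0.8, 0.6, 0.4, 0.2):
        sub = stratified_subsample(train, ratio, seed=0)
        counts = sorted(set(sub.class_counts().values()))
        print(f"  ratio {ratio:>4}: {len(sub):>3} labeled "
              f"(per-class counts {counts})")
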