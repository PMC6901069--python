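"""Run the QC stages by hand: screen, pair-sync, merge, primer, filter.

Shows the per-stage read attrition that the pipeline's summary step
compiles automatically.
"""

import tagcascade as tc
from tagcascade import read_qc
from tagcascade.simulate import synthetic_adapter, synthetic_phix

cfg = tc.MockConfig(n_taxa=6, n_samples=1, n_reads=1500, seed=2)
run = tc.simulate_reads(cfg)

res1 = tc.screen_contaminants(run.r1, [synthetic_phix()], [synthetic_adapter()])
res2 = tc.screen_contaminants(run.r2, [synthetic_phix()], [synthetic_adapter()])
print(f"screen      : {res1.counts['phix'] + res2.counts['phix']} PhiX, "
      f"{res1.counts['contaminant'] + res2.counts['contaminant']} adapter reads removed")

pairs, orphans = tc.sync_pairs(res1.kept, res2.kept)
print(f"sync        : {len(pairs)} pairs kept, {orphans} orphans discarded")

merged = [m for f, r in pairs if (m := tc.merge_pairs(f, r)) is not None]
print(f"merge       : {len(merged)} overlapping pairs assembled")

spec = read_qc.PrimerSpec(cfg.primer_fwd, cfg.primer_rev)
trimmed = [t for m in merged if (t := tc.handle_primers(m, spec)) is not None]
print(f"primer      : {len(trimmed)} reads with both primers located and clipped")

passed = [t for t in trimmed if tc.quality_filter(t)[0]]
print(f"qfilter     : {len(passed)} reads pass (mean Q >= 27, <= 1 N, <= 5 bases < Q15)")
print()
print("Each stage can only discard reads; the retained counts are the")
print("monotone trajectory the read-count summary asserts.")
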