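"""The OTU cascade: dereplicate, denoise at 99%, abundance floor,
chimera scans, final 97% clusters.

Reads are simulated error-free here so the expected outcome is exact:
one final OTU per template.
"""

import tagcascade as tc
from tagcascade.clustering import CascadeParams

templates = tc.generate_templates(10, 250, 0.10, seed=3)
reads = [
    tc.SeqRecord(f"{t.record.id}.{i}", t.record.seq)
    for t in templates
    for i in range(100)
]
refs = [t.record for t in templates]

final, counts = tc.run_cascade(reads, CascadeParams(min_cluster_size=25), refs)
print(f"input reads            : {counts['input_reads']}")
print(f"unique sequences       : {counts['unique_sequences']}")
print(f"99% denoised clusters  : {counts['denoised_clusters']}")
print(f"after abundance >= 25  : {counts['clusters_after_size_filter']}")
print(f"after chimera scans    : {counts['clusters_after_chimera_ref']}")
print(f"final 97% OTUs         : {counts['final_clusters']} "
      f"(expected {len(templates)}: one per template)")
print(f"reads in final OTUs    : {counts['clustered_reads']}")
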