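#!/usr/bin/env python
"""Quality-filter the quantification table and measure replicate overlap.

Removes records carrying disqualifying search-engine flags and peptides
outside the 8-11-mer window, then reports the per-reason removal counts
and the pairwise Jaccard similarity of replicate peptide sets.
"""

from pathlib import Path

from ligandscape import peptide_io

OUT = Path("results/analysis")

records = peptide_io.read_quant_table(OUT / "records.tsv")
filtered, report = peptide_io.apply_quality_filters(records)
consensus, jaccard = peptide_io.replicate_consensus(filtered)

peptide_io.write_quant_table(filtered, OUT / "filtered.tsv")
peptide_io.write_filter_report(report, OUT / "filter_report.json")

print(f"kept {len(filtered)} of {len(records)} records")
print(f"removed per reason: {report}")
for (a, b), j in jaccard.items():
    print(f"Jaccard({a}, {b}) = {j:.3f}")
print(f"{len(consensus)} peptides seen in every replicate")
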