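"""Recompute the cross-species NoLS prediction accuracy table.

Loads the packaged benchmark (31 experimentally determined NoLSs in 27
eukaryotic and viral proteins, with the intervals the original detector
reported on each), applies the 60%-of-shortest overlap criterion, and
prints sensitivity, positive predictive value and per-protein
specificity per taxon/host group and overall.
"""

import nolscan as n

records = n.load_benchmark()
table = n.compute_metrics(records, min_overlap=0.6)

print(table.rounded().to_string(na_rep="N/A"))
print()
pct = table.overall_percent()
print(f"overall: sensitivity {pct['sensitivity']}%, "
      f"PPV {pct['ppv']}%, specificity {pct['specificity']}%")
print("# sensitivity = detected NoLSs / all experimental NoLSs;")
print("# PPV = true-positive predictions / all predictions;")
print("# specificity = proteins with no false-positive segment / all proteins")
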