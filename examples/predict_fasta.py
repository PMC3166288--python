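"""Scan a small FASTA batch for NoLSs with the bundled model.

Builds two sequences in memory — one synthetic protein with a planted
lysine/arginine-rich motif, one plain background protein — scores every
13-residue window, calls 20-residue segments whose mean window score
reaches 0.8, and prints the default (MEDIUM) clinod-style report:
sequence name, number of NoLSs, their positions and their sequences.
"""

import nolscan as n
from nolscan.cli import default_model

model = default_model()

with_motif, truth = n.generate_protein(150, n_motifs=1, seed=11,
                                       name="planted_motif")
background, _ = n.generate_protein(150, n_motifs=0, seed=12,
                                   name="background_only")

results = []
for record in (with_motif, background):
    intervals, segments = n.predict(record, model)
    results.append((record, intervals, segments))

print(n.render_batch(results, n.OutputFormat.MEDIUM), end="")
print(f"# ground truth for planted_motif: {truth[0].start}-{truth[0].end}")
print("# a predicted interval is correct when it covers >= 60% of the "
      "shorter of the two")
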