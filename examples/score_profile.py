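"""Per-residue NoLS score profile for one protein.

Scores a synthetic protein with a planted motif, averages each run of 8
consecutive window scores into a 20-residue segment score, and prints a
text sparkline of the per-residue profile with the calling threshold
marked — the same profile the optional matplotlib helper
(`nolscan.segment_caller.plot_profile`) draws as a line chart with the
0.8-1.0 calling band shaded.
"""

import nolscan as n
from nolscan.cli import default_model

model = default_model()
record, truth = n.generate_protein(120, n_motifs=1, seed=5, name="demo")
intervals, segments = n.predict(record, model)
profile = n.residue_profile(segments)

print(f"{record.name}: planted motif {truth[0].start}-{truth[0].end}, "
      f"predicted {', '.join(str(iv) for iv in intervals) or 'no NoLS'}")
bars = " .:-=+*#%@"
line = "".join(bars[min(int(s * 10), 9)] for s in profile)
print(line)
print("".join("^" if truth[0].start <= i <= truth[0].end else " "
              for i in range(1, len(profile) + 1)))
print("# one character per residue; darker = higher mean segment score "
      "(>= 0.8 is called); ^ marks the planted motif")
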