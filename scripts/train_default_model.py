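"""Regenerate the bundled default model from the synthetic corpus.

The packaged model (src/nolscan/data/default_model.json) exists so the
CLI and examples work out of the box; it is trained on the synthetic
K/R-motif corpus with a fixed seed, so this script reproduces it
byte-for-byte. Run from the repository root:

    python scripts/train_default_model.py
"""

from pathlib import Path

import nolscan as n

SEED = 20110803

ts = n.generate_training_set(2000, 2000, seed=SEED)
train_pos, train_neg, heldout_pos, heldout_neg = ts.split()
model = n.train(train_pos, train_neg, seed=SEED)

correct_pos = sum(model.score_window(w) >= 0.5 for w in heldout_pos)
correct_neg = sum(model.score_window(w) < 0.5 for w in heldout_neg)
acc = (correct_pos + correct_neg) / (len(heldout_pos) + len(heldout_neg))
model.training_metadata["corpus"] = "synthetic K/R-motif windows 2000+2000"
model.training_metadata["heldout_window_accuracy"] = acc

out = Path(__file__).resolve().parents[1] / "src/nolscan/data/default_model.json"
n.save_model(model, out)
print(f"wrote {out} (heldout window accuracy {acc:.3f}, "
      f"{model.training_metadata['epochs_run']} epochs)")
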