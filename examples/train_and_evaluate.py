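"""Train a window scorer from scratch on the synthetic corpus.

Generates 1,000 positive (motif) and 1,000 negative (background) 13-mer
windows, trains the feed-forward scorer with a fixed seed, and reports
held-out window accuracy — then saves the model as self-describing JSON
and proves the reload is bit-exact.
"""

import io

import nolscan as n

corpus = n.generate_training_set(1000, 1000, seed=7)
train_pos, train_neg, held_pos, held_neg = corpus.split()
model = n.train(train_pos, train_neg, seed=7)

meta = model.training_metadata
print(f"trained on {len(train_pos)} + {len(train_neg)} windows, "
      f"{meta['epochs_run']} epochs, final loss {meta['final_train_loss']:.4f}")

correct = sum(model.score_window(w) >= 0.5 for w in held_pos)
correct += sum(model.score_window(w) < 0.5 for w in held_neg)
total = len(held_pos) + len(held_neg)
print(f"held-out window accuracy: {correct}/{total} = {correct/total:.3f}")

buf = io.StringIO()
n.save_model(model, buf)
reloaded = n.load_model(io.StringIO(buf.getvalue()))
window = held_pos[0]
print(f"score of one held-out motif window {window}: "
      f"{model.score_window(window):.4f} "
      f"(reload identical: {model.score_window(window) == reloaded.score_window(window)})")
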