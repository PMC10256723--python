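"""Random hyperparameter search for closed-loop forecast quality.

Uniform samples in the parameter box (recurrent strength/length and input
strength in (0, 0.2), conduction speed in (0, 0.1)) are scored by the
total SSIM of the bump forecast.  A small network keeps this demo fast;
scripts/acceptance.py runs the full-scale version.
"""

import numpy as np

from wavecast import bump_objective, random_search

res = random_search(bump_objective(n_side=16, frames_per_cycle=40), n_samples=8, seed=0)
for s, v in zip(res.samples, res.values):
    print(
        f"alpha={s['alpha']:.3f} beta={s['beta']:.3f} gamma={s['gamma']:.3f} "
        f"v={s['v']:.3f} -> total SSIM {v:.3f}"
    )
print(f"best: {res.best_value:.3f} at sample {res.best_index}")
print("best-so-far trace:", np.round(res.best_so_far(), 3))
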