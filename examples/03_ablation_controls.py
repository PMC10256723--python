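"""What breaks forecasting: recurrence removal and topology shuffles.

Each control retrains the readout from scratch on the modified network, so
any failure is a failure of the network dynamics, not of stale weights.
The noise-calibrated threshold is the total SSIM of the ground truth
against a heavily noise-corrupted copy of itself — scores below it mean
"no better than noise".
"""

from wavecast import BUMP_PARAMS, ablation_suite, bump_experiment, calibrate_threshold

results = ablation_suite(
    bump_experiment, BUMP_PARAMS, n_side=50, seed=0,
    modes=("intact", "no_recurrence", "weights_and_delays"),
)
threshold = calibrate_threshold(results["intact"].truth_centered, seed=0)
print(f"noise-calibrated failure threshold: {threshold:.3f}")
for mode, exp in results.items():
    print(f"{mode:20s} total SSIM = {exp.score.total:.4f}")
print("Removing recurrence leaves only the feedforward imprint and the")
print("forecast collapses; the structured wave dynamics carry the movie.")
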