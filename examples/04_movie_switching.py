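"""Switching between two learned movies without retraining.

Two readouts are trained on two different synthetic walker movies over the
*same* recurrent network and stored in the aggregate V = c·V1 + (1−c)·V2.
While a movie drives the network, the mixing coefficient c climbs toward
the readout whose output matches the input (SSIM feedback, directional
hill-climb rule); forecasting then replays the recalled movie.
"""

from wavecast import Movie, build_topology, run_switch_experiment
from wavecast.dynamics import run
from wavecast.experiments import BUMP_PARAMS
from wavecast.readout import assemble_regression, train_readout
from wavecast.stimuli import synthetic_walker

fphc = 20  # short cycle keeps this demo quick
n_side = 30
movie1 = synthetic_walker(n_cycles=5, out_shape=(40, 26), frames_per_half_cycle=fphc, seed=0)
movie2 = synthetic_walker(n_cycles=5, out_shape=(40, 26), frames_per_half_cycle=fphc, seed=1)
cycle = 2 * fphc
top = build_topology(n_side, BUMP_PARAMS)

models = []
for mv in (movie1, movie2):
    hist = run(Movie(mv.frames[: 4 * cycle]), top)
    models.append(train_readout(assemble_regression(hist, mv, start=cycle, T=3 * cycle)))

schedule = [(0, 2 * cycle, cycle), (1, 2 * cycle, cycle)]  # drive 1, forecast, drive 2, forecast
trace = run_switch_experiment(top, tuple(models), (movie1, movie2), schedule, rule="directional")

drive1_end = 2 * cycle - 1
drive2_end = 5 * cycle - 1
print(f"c after driving with movie 1: {trace.c[drive1_end]:.2f}  (1.0 selects V1)")
print(f"c after driving with movie 2: {trace.c[drive2_end]:.2f}  (0.0 selects V2)")
print("The coefficient commits to whichever stored readout matches the input stream.")
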