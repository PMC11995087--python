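"""Build the two conditioning designs and inspect their trial structure.

Experiment 1 is simple conditioning (one reinforced circle, CS+), Experiment
2 differential conditioning (CS+ and CS-).  The printed counts are the
design constants everything downstream relies on.
"""

import percgen as pg

for experiment in (1, 2):
    stimset = pg.make_stimulus_set(experiment)
    schedule = pg.make_schedule(experiment, seed=7)
    df = schedule.to_frame()
    print(f"Experiment {experiment}: {len(schedule)} trials")
    print(f"  CS+ = {stimset.cs_plus} ({stimset.diameter(stimset.cs_plus):.2f} mm), "
          f"CS- = {stimset.cs_minus}")
    print(f"  acquisition trials: {(df.phase == 'ACQUISITION').sum()}, "
          f"reinforced CS+: {int(df[df.phase == 'ACQUISITION'].reinforced.sum())}")
    print(df.groupby(["phase", "block"]).size().rename("trials").to_string(), "\n")

# 198 = 14 acquisition + 4 blocks of 46; 186 = 24 acquisition + 3 blocks of 54.
# The US (shock) only ever appears on CS+ trials; CS- carries outcome -1,
# the no-shock signal that drives inhibitory learning.
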