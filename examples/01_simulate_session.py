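"""Simulate one walk-and-reach session and inspect its structure.

Generates 200 trials of the memory-guided task (8 targets = 2 distances x 4
positions) with a 10% premature-release rate, and prints the condition and
outcome breakdown plus one trial's event sequence.
"""

from walkreach.config import CageGeometry, TaskConfig
from walkreach.simulate import generate_task_trials

trials, events = generate_task_trials(
    TaskConfig(), CageGeometry(), n_trials=200, error_rates={"premature": 0.1}, seed=1
)

print("outcomes:")
print(trials["outcome"].value_counts().to_string())
print("\ntrials per condition:")
print(trials.groupby(["distance", "position"]).size().to_string())
print("\nevent sequence of trial 0 (ms on the session clock):")
print(events[events["trial_id"] == 0].to_string(index=False))

# The memory period (cue_off -> go) varies 400-2000 ms by design; premature
# trials release before the 200 ms lock-out after the go cue and carry no
# acquisition event.
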