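"""Build the visual-category protocol and simulate an iEEG session.

The protocol presents scene, object and face photographs (100 unique pictures
x 2 repeats each) plus a 25 x 2 fruit/vegetable target set the subject
responds to by keypress: 650 stimuli of 300 ms every 1,100 ms, in blocks of
five separated by 3-s pauses.  The simulator then plants event-locked
multiplicative broadband-gamma gain responses on chosen bipolar channels in
1/f background noise, with occasional interictal spikes.
"""

import numpy as np

from bgamap import build_protocol, default_protocol, make_study_session

# --- the full 650-stimulus study protocol -------------------------------
events = build_protocol(default_protocol(seed=0))
print(f"events: {len(events)}")
print(events["trial_type"].value_counts().to_string())
print(f"session span: {events['onset'].iloc[-1] + 1.1:.1f} s")
print(events.head(6).to_string(index=False))

# --- a scaled-down simulated session ------------------------------------
session = make_study_session(
    seed=0,
    n_scene=3,      # scene-selective bipolar channels
    n_object=3,     # object-selective
    n_null=4,       # non-responsive
    n_unique=15,    # 15 unique pictures/category (x2 repeats)
    gain=0.4,       # +40% gamma gain ...
    onset=0.2,      # ... starting 200 ms after picture onset ...
    duration=0.3,   # ... for 300 ms
)
rec = session.recording
print(f"\nrecording: {rec.n_channels} contacts, {rec.duration:.1f} s at {rec.fs:.0f} Hz")
print(f"spike annotations: {len(session.annotations)}")
print("planted truth:")
for name, label in zip(session.ground_truth.channel, session.ground_truth.label):
    print(f"  {name}: {label}")
print(f"signal RMS: {np.sqrt(np.mean(rec.signal**2)) * 1e6:.1f} uV")
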