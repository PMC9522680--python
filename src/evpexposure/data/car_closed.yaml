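# Closed car shared by 2 users among 4 occupants, 1-h exposure.
# ach is not a measured value: it is reconstructed by calibrating the
# transient box-model average against the nicotine non-user intake for this
# space (see calibrate_ach); treat as a modeling default, not data.
name: car_closed
volume_m3: 3.17
ach_per_h: 25.0621
duration_h: 1.0
n_users: 2
n_occupants: 4
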