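# Meeting room, 3 users among 15 occupants, 4-h exposure.
# ach reconstructed by calibration (see car_closed.yaml).
name: meeting_room
volume_m3: 81.0
ach_per_h: 1.6366
duration_h: 4.0
n_users: 3
n_occupants: 15
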