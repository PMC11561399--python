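# Example run configuration. Every key is optional; omitted keys use the
# package defaults. Section reference: gate, controller, trend, sim, paths,
# actuator, run, channel_map.

[gate]
fsc_min = 10000
fl3_threshold = 1000
fl1_threshold = 1500
min_events = 500

[controller]
rate_ladder = 1 1.5 3 5
pi_max = 35
dwell_samples = 3

[trend]
alpha = 0.5
k = 3

[sim]
primary_rate = 6.24
feed_fur = 6.9
secondary_fur = 50
events_per_sample = 5000
seed = 0

[paths]
watch_dir = fcs_in
out_dir = out

[actuator]
kind = mock

[run]
poll_interval = 60
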