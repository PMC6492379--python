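"""Simulate the uncalibrated default bench and report its pressure state.

Assembles the default network (0.31 ml/mmHg cranial and 0.84 ml/mmHg spinal
air chambers, three-segment spinal canal), drives it with the default 0.8 ml
AV waveform at 70 bpm, discards two warm-up cycles and records nine.
"""

import csftwin as ct

cfg = ct.load_config(None)
net = ct.assemble(cfg)
av = ct.default_av_waveform()
res = ct.simulate(net, av, n_cycles=9, warmup_cycles=2)

segments = ct.cycle_split(res.time, res.icp, period_hint=res.period)
pulse = ct.icp_stats(segments)
flow = res.cycle_mean_flow()

print(f"mean ICP               : {res.icp.mean():7.2f} mmHg  (baseline {cfg.baseline_icp_mmHg})")
print(f"ICP range              : {res.icp.min():7.2f} .. {res.icp.max():.2f} mmHg")
print(f"pulse amplitude (MWA)  : {pulse.mwa:7.2f} mmHg")
print(f"spinal flow extrema    : {flow.values.max():7.2f} / {flow.values.min():.2f} ml/min")
print(f"spinal stroke volume   : {ct.stroke_volume(flow):7.3f} ml/CC")

# The mean ICP sits at the configured operating point because the AV waveform
# carries zero net volume: the sealed system cannot drift.
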