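"""Construct the arteriovenous (AV) driving waveform from its components.

The arterial inflow to the cranium is modeled as a baseline plus a narrow
systolic lobe; the venous outflow is the same curve delayed and flattened.
After volume matching, their difference is the AV flow: the net pulsatile
volume load that displaces CSF (Monro-Kellie), scaled to a 0.8 ml stroke.
"""

import csftwin as ct

arterial = ct.generate_arterial()
venous = ct.match_venous_volume(arterial, ct.derive_venous(arterial))
av = ct.scale_to_stroke_volume(ct.av_flow(arterial, venous), 0.8)

print(f"arterial mean flow     : {arterial.values.mean():8.2f} ml/min")
print(f"arterial cycle volume  : {arterial.cycle_volume():8.3f} ml")
print(f"venous cycle volume    : {venous.cycle_volume():8.3f} ml  (matched)")
print(f"AV net cycle volume    : {av.cycle_volume():8.1e} ml  (exactly closed)")
print(f"AV stroke volume       : {av.positive_lobe_volume():8.3f} ml")
print(f"AV extrema             : {av.values.max():8.2f} / {av.values.min():.2f} ml/min")

# The stroke volume is the volume pushed into the cranium per heartbeat; the
# zero net volume reflects the rigid cranium: whatever enters must leave.
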