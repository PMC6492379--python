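"""Turn the AV waveform into a manufacturable cam-disc contour.

The piston pump realizes the AV flow by a cam rotating once per cardiac
cycle.  The cam lift is the running displaced volume divided by the piston
area (displacement/hodograph transformation); the contour closes because the
AV flow carries zero net volume.
"""

import csftwin as ct

av = ct.default_av_waveform()
profile = ct.cam_from_waveform(av, base_radius=20.0, bore_mm=9.0)
ct.export_profile(profile, "cam_profile.csv")

print(f"piston area            : {profile.piston_area:7.2f} mm^2  (9 mm bore)")
print(f"base radius            : {profile.base_radius:7.2f} mm")
print(f"maximum lift           : {profile.max_lift:7.2f} mm")
print(f"implied stroke volume  : {profile.max_lift * profile.piston_area / 1000:7.3f} ml")
print("contour written to cam_profile.csv (theta_rad, r_mm, x_mm, y_mm)")

# Maximum lift ~ stroke volume / piston area: 800 mm^3 over 63.6 mm^2 gives
# the ~12.6 mm stroke the follower must travel each cycle.
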