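"""Calibrate the two cranial valve resistances against bench flow extrema.

The bench reported mean bidirectional spinal-flow maxima of 133.60 ml/min
(caudal) and -68.01 ml/min (cranial).  The valve settings that produced them
are not known, so the twin recovers them by a deterministic bounded fit.
"""

import csftwin as ct

net = ct.assemble(ct.load_config(None))
av = ct.default_av_waveform()

fit = ct.calibrate_resistances(net, av, target_caudal_max=133.60, target_cranial_max=-68.01)

print(f"converged              : {fit.converged} ({fit.n_evaluations} simulations)")
print(f"parenchyma-path R      : {fit.r_parenchyma_path:8.4f} mmHg/(ml/min)")
print(f"cranial-SAS valve R    : {fit.r_valve2:8.4f} mmHg/(ml/min)")
print(f"parallel combination   : {fit.r_parallel:8.4f} mmHg/(ml/min)  (the identifiable quantity)")
print(f"achieved extrema       : {fit.achieved_caudal_max:8.2f} / {fit.achieved_cranial_max:.2f} ml/min")
print(f"relative residuals     : {fit.residuals[0]:+.3%} / {fit.residuals[1]:+.3%}")

# The spinal flow senses the two cranial paths only through their parallel
# resistance, so any (R_path, R_valve2) pair with the right parallel value
# reproduces the extrema; the split changes only the internal ICP tap.
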