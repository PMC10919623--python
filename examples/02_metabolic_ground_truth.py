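"""Derive the criterion measure: resting VO2, steady-state METs, intensity.

Resting VO2 is the minutes-6-to-9 average of the 10-minute seated rest.
Each bout's steady-state VO2 (longest flat suffix, final 3 minutes
averaged) divided by resting VO2 gives METs; METs map to four intensity
classes at 1.5 / 3.0 / 6.0.  Bouts with no steady segment are excluded --
exactly what happens to participants who never settle metabolically.
"""

import wearsite as ws

p = ws.sample_participants(1, 0, seed=3)[0]
protocol = ws.draw_protocol(p, seed=4)
series, latents = ws.simulate_calorimetry(p, protocol, seed=5)

rest = ws.resting_vo2(series)
print(f"resting VO2 estimate: {rest:.2f} ml/kg/min "
      f"(latent value {p.resting_vo2:.2f})")

print(f"\n{'bout':<6}{'activity':<28}{'steady VO2':>11}{'METs':>7}"
      f"{'intensity':>11}{'latent MET':>12}")
results = [ws.groundtruth.bout_result(series, lat.bout_index, lat.start_s,
                                      lat.end_s, rest)
           for lat in latents]
for lat, res, bout in zip(latents, results, protocol.bouts):
    if res.excluded:
        print(f"{lat.bout_index:<6}{bout.activity.name:<28}"
              f"{'excluded: ' + res.exclusion_reason:>41}")
    else:
        print(f"{lat.bout_index:<6}{bout.activity.name:<28}"
              f"{res.steady_vo2:>11.2f}{res.mets:>7.2f}{res.intensity:>11}"
              f"{lat.met_draw:>12.2f}")
# Recovered METs should sit within a few percent of the latent draws; the
# intensity label is the bout-level ground truth every window inherits.
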