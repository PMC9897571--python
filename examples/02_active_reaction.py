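"""Active reaction of the femur-tibia joint and its absence in the outer leg.

A slow elongation ramp of the fCO apodeme (<= 2 mm/s, the assistance
band) activates state Stance.  During straight forward walking the ring
net then drives the flexor - an assistance ("active") reaction; during
backward walking the extensor.  In curve walking the inner front leg
keeps the flexor reaction while the outer leg shows only a weak
extensor response.  The levator response of the coxa-trochanterofemur
joint shows no such reversal.
"""

from insectleg import build_catalog, classify_reflex, run_scenario

catalog = build_catalog()
for sid, joint in [("exp321_fw", "gamma"), ("exp321_bw", "gamma"),
                   ("exp322_inner", "gamma"), ("exp322_outer", "gamma"),
                   ("exp33", "beta"), ("exp321_bw", "beta")]:
    outcome = classify_reflex(run_scenario(catalog[sid]), joint)
    print(f"{sid:13s} {joint}: {outcome.dominant_channel:9s} "
          f"({outcome.strength}, mean {outcome.mean_dominant:.1f} mV)")

print()
print("fCO elongation assists the ongoing stance movement (flexor forward,")
print("extensor backward, flexor in the inner leg); the outer leg's weak")
print("extensor response marks the absence of an active reaction, and the")
print("levator response is identical in both walking directions.")
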