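"""Context-dependent reflex reversal of the thorax-coxa joint.

Bending the femur caudally loads the campaniform sensilla and, through
the Swing/Stance selection, drives one antagonist of the alpha joint.
Which one depends on walking direction: the retractor during forward
walking, the protractor during backward walking - the same stimulus,
two opposite motor responses.
"""

from insectleg import build_catalog, classify_reflex, run_scenario

catalog = build_catalog()
for sid in ("exp31_fw", "exp31_bw"):
    result = run_scenario(catalog[sid])
    bend = classify_reflex(result, "alpha", phase="stimulus")
    relax = classify_reflex(result, "alpha", phase="relax")
    print(f"{sid}: bending -> {bend.dominant_channel} "
          f"(mean {bend.mean_dominant:.1f} mV, ratio {bend.dominance_ratio:.1f}); "
          f"relaxation -> {relax.dominant_channel}")

print()
print("The dominant channel flips retractor <-> protractor with walking")
print("direction: a reflex reversal produced purely by the motivation-unit")
print("context, not by any change in the sensory pathway itself.")
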