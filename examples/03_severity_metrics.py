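"""Coarctation severity from cross-section measurements.

Computes hydraulic diameters (D_h = 4A/P) and coarctation ratios
(coarctation D_h over descending-aorta D_h) for three repair states of the
same vessel, plus the outlet extrusion length (10 x D_h) used when
preparing the CFD geometry.
"""

from echobc import (
    CrossSection,
    PatchGeometry,
    extension_length,
    geometry_report,
)

# (label, lumen area mm^2, perimeter mm) at the narrowest coarctation
# section for pre-repair, post-repair and hypothetical healthy states
sections = [
    PatchGeometry(CrossSection(8.08, 9.59, "pre_repair")),
    PatchGeometry(CrossSection(25.91, 17.99, "post_repair")),
    PatchGeometry(CrossSection(61.82, 27.61, "healthy")),
]
dao = PatchGeometry(CrossSection(48.25, 24.66, "descending_aorta"))

table = geometry_report(sections, dao)
print(table.round(2).to_string(index=False))

print("\na ratio near 0.4 marks a severe stenosis; near 1.0, none.")
print(f"descending-aorta outlet extrusion: {extension_length(dao):.1f} mm "
      f"(10 x D_h keeps recirculation away from the outlet patch)")
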