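"""Map flower reflectance spectra into the bee colour hexagon.

Builds the six archetypal flower spectra, converts each to a hexagon
colour locus under the default green-leaf background and D65 daylight,
and prints the locus table.  Hue is the angle in bee colour space
(BLUE vertex at 90°), contrast the distance from the adapting
background at the centre, and the sector the bee's colour category.
"""

from beehex import spectrum_to_locus
from beehex.synth import ARCHETYPES

print(f"{'archetype':24s} {'x':>7s} {'y':>7s} {'hue°':>7s} {'contrast':>9s}  sector")
for name, arch in ARCHETYPES.items():
    locus = spectrum_to_locus(arch.reflectance())
    print(
        f"{name:24s} {locus.x:7.3f} {locus.y:7.3f} {locus.hue_deg:7.1f} "
        f"{locus.contrast:9.3f}  {locus.sector}"
    )

print(
    "\nEach row is one flower type as a trichromatic bee sees it: "
    "a human-white flower that absorbs UV lands in BLUE-GREEN (BG), "
    "a UV-reflecting yellow in UV-GREEN (UG)."
)
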