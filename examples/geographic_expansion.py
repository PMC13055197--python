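"""Geographic expansion potential (GEP) from 1-km point-buffer unions.

Three sporophyte records and two gametophyte-only records 5 km away: the
species' occupied area is partitioned into the sporophyte buffer union
(s_geo) and the extra area contributed by gametophytes only (g_geo), and
GEP = g_geo / (g_geo + s_geo).
"""

import fernexpand as fx

KM = 1 / 111.195  # ~1 km in degrees of latitude

spor = [(0.0, 0.0), (0.0, 2 * KM), (0.0, 4 * KM)]
gam = [(0.0, 9 * KM), (0.0, 11 * KM)]

part = fx.partition_geographic_area(gam, spor, radius_km=1.0)
gep = fx.compute_gep(part, as_percent=True)

print(f"sporophyte area      s_geo = {part.s_geo:6.2f} km^2")
print(f"gametophyte-only area g_geo = {part.g_geo:6.2f} km^2")
print(f"GEP = {gep:.1f}%")
print()
print("Two fifths of this species' buffered range is occupied by "
      "gametophytes beyond the sporophyte distribution; a GEP of 0 would "
      "mean every gametophyte record sits inside sporophyte-occupied area.")
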