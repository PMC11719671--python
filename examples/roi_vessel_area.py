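"""Region-of-interest helpers: endpoint extrapolation and vessel area.

When only a circular sector of the outgrowth halo is evaluated (as when
comparing culture matrices), endpoint counts are scaled to the full ring by
the sector angle, and a vessel area is computed from the maximum outgrowth
radius and the same angle.
"""

from angioring import roi_extrapolate_endpoints, vessel_area

counted = 101          # endpoints counted inside the ROI
sector_angle = 90.0    # degrees
r_max = 1448.0         # um, maximum outgrowth radius in the ROI

per_ring = roi_extrapolate_endpoints(counted, sector_angle)
print(f"{counted} endpoints in a {sector_angle:.0f} degree sector "
      f"-> {per_ring:.0f} endpoints per ring")

area = vessel_area(r_max, sector_angle, mode="sector")
print(f"sector vessel area at r_max {r_max:.0f} um: {area:.3f} mm^2")

area_annulus = vessel_area(r_max, sector_angle, mode="annulus_sector",
                           r_ring_um=540.0)
print(f"annulus-sector area outside a 540 um ring:   {area_annulus:.3f} mm^2")
# the sector mode treats the outgrowth as a pie slice from the ring centre;
# the annulus mode measures only the band beyond the explant's own radius.
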