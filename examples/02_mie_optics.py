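"""Per-grain Mie optics across a sample's size range.

For Gd2O2S grains (index 2.3 + 1e-5i) in a 1.35 binder at the Tb
emission line (545 nm), the extinction efficiency oscillates with grain
diameter (the interference structure of Mie scattering), scattering is
strongly forward-peaked (g > 0.5), and the single-grain albedo is close
to but below one, so light survives thousands of scatterings before
absorption becomes likely.
"""

import screenlight as sl

optics = sl.OpticalConstants.for_activator("Tb")
print("d (um)      x     Q_ext    g      albedo   m_ext (1/um)")
for d in [0.6, 1.0, 1.232, 2.0, 3.0, 3.492]:
    r = sl.mie_single(d, optics)
    m_ext = sl.extinction_coefficient(r, packing_fraction=0.5)
    print(f"{d:5.3f}  {r.x:7.2f}  {r.q_ext:6.3f}  {r.g:.3f}  {r.albedo:.6f}"
          f"  {m_ext:.3f}")
# m_ext ~ 1/um means optical mean free paths below a micron: a 100 um
# screen is optically thick, and photon transport is strongly diffusive.

gsd = sl.fit_sample("UKL65/UF-R1")
table = sl.mie_table(gsd, optics, packing_fraction=0.5)
print(f"\ntabulated {len(table.diameters_um)} nodes at "
      f"{table.grid_step*1000:.0f} nm steps over "
      f"[{gsd.lower_um}, {gsd.upper_um}] um")
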