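"""Unit conversions tying the lead model study to the plutonium application.

Accumulation time -> maximal equivalent dose; mass-fraction concentration ->
amount of substance in the interrogated wound volume; amount -> activity.
A long half-life means many atoms per becquerel, which is exactly why
atom-counting (XRF) beats photon-counting for plutonium.
"""

import woundxrf as wx

print("accumulation time -> maximal equivalent dose (3.3 mSv/s):")
for s in (5, 10, 15, 20):
    print(f"  {s:3d} s -> {wx.dose_from_time(s):5.1f} mSv")

print("\nphantom recipe: paint solution ppm -> phantom ppm at 1:99 mixing")
for stock in (0, 200, 500, 1000, 1500, 2000):
    print(f"  {stock:5d} ppm solution -> {wx.phantom_concentration(stock):5.1f} ppm phantom")

geom = wx.MeasurementGeometry()  # 8 mm beam, 10 mm depth, 1.06 g/cm^3
print(f"\nmeasured volume: {geom.volume_cm3:.3f} cm^3, mass {geom.mass_g:.3f} g")

nmol = wx.concentration_to_amount(1.2, geom)
print(f"1.2 ppm lead in that volume = {nmol:.2f} nmol")

for name in ("Pu-239", "Pu-240", "Am-241"):
    bq = wx.amount_to_activity(nmol, wx.NUCLIDES[name])
    print(f"  {nmol:.2f} nmol of {name:6s} = {bq/1e3:8.2f} kBq")

print("\n(The ~1.7 kBq of Pu-239 at the 1.2 ppm limit is below the activities "
      "reported for historical wound-contamination incidents, which is what "
      "makes the method practically useful.)")
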