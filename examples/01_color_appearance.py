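"""Forward color appearance transforms: sRGB codes -> IPT and CAM16 correlates.

Takes a few display colors (a warm white, a cool white, a saturated red,
mid gray), converts them to D65-referred XYZ, and prints lightness J,
chroma c and hue angle h in both appearance spaces.  IPT correlates are
scaled to the 0-100 range so the two spaces can be compared dimension by
dimension; CAM16 uses the package's default viewing conditions (L_A = 20
cd/m^2, Y_b = 20, average surround).
"""

import numpy as np

from cabinlight import cam16_from_xyz_rel, ipt_correlates, srgb_to_xyz, xyz_to_ipt

colors = {
    "warm white (3000 K-ish)": (255, 185, 110),
    "cool white (6500 K-ish)": (250, 250, 255),
    "saturated red": (220, 40, 30),
    "mid gray": (119, 119, 119),
}

print(f"{'color':26s} {'space':6s} {'J':>7s} {'c':>7s} {'h':>7s}")
for name, rgb8 in colors.items():
    xyz = srgb_to_xyz(np.array(rgb8) / 255.0)
    ipt = ipt_correlates(xyz_to_ipt(xyz))
    cam = cam16_from_xyz_rel(xyz)
    print(f"{name:26s} {'IPT':6s} {float(ipt.J):7.2f} {float(ipt.c):7.2f} {float(ipt.h):7.1f}")
    print(f"{'':26s} {'CAM16':6s} {float(cam.J):7.2f} {float(cam.c):7.2f} {float(cam.h):7.1f}")

print()
print("J is lightness (0-100), c chroma, h hue angle in degrees.")
print("The two spaces agree closely on J and disagree more on chroma,")
print("which is why the analysis carries both throughout.")
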