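"""One-off: write 5 nm CIE 1931 2-deg CMF and D65 tables (400-780 nm) into the
package data directory, linearly interpolated from the canonical 10 nm tabulations."""
import numpy as np
import pathlib

wl10 = np.arange(400, 781, 10)

xbar10 = np.array([
    0.0143, 0.0435, 0.1344, 0.2839, 0.3483, 0.3362, 0.2908, 0.1954, 0.0956,
    0.0320, 0.0049, 0.0093, 0.0633, 0.1655, 0.2904, 0.4334, 0.5945, 0.7621,
    0.9163, 1.0263, 1.0622, 1.0026, 0.8544, 0.6424, 0.4479, 0.2835, 0.1649,
    0.0874, 0.0468, 0.0227, 0.0114, 0.0058, 0.0029, 0.0014, 0.0007, 0.0003,
    0.00017, 0.00008, 0.00004,
])
ybar10 = np.array([
    0.0004, 0.0012, 0.0040, 0.0116, 0.0230, 0.0380, 0.0600, 0.0910, 0.1390,
    0.2080, 0.3230, 0.5030, 0.7100, 0.8620, 0.9540, 0.9950, 0.9950, 0.9520,
    0.8700, 0.7570, 0.6310, 0.5030, 0.3810, 0.2650, 0.1750, 0.1070, 0.0610,
    0.0320, 0.0170, 0.0082, 0.0041, 0.0021, 0.00105, 0.00052, 0.00025,
    0.00012, 0.00006, 0.00003, 0.000015,
])
zbar10 = np.array([
    0.0679, 0.2074, 0.6456, 1.3856, 1.7471, 1.7721, 1.6692, 1.2876, 0.8130,
    0.4652, 0.2720, 0.1582, 0.0782, 0.0422, 0.0203, 0.0087, 0.0039, 0.0021,
    0.0017, 0.0011, 0.0008, 0.0003, 0.0002, 0.00005, 0.00002, 0.0, 0.0, 0.0,
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
])
d65_10 = np.array([
    82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86, 115.92,
    108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05, 100.00, 96.33,
    95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03, 80.21, 82.28,
    78.28, 69.72, 71.61, 74.35, 61.60, 69.89, 75.09, 63.59, 46.42, 66.81,
    63.38,
])

assert all(len(a) == len(wl10) for a in (xbar10, ybar10, zbar10, d65_10))

wl5 = np.arange(400, 781, 5)
out = pathlib.Path(__file__).resolve().parents[1] / "src" / "savelight" / "data"
out.mkdir(parents=True, exist_ok=True)

with open(out / "cie1931_2deg_5nm.csv", "w") as fh:
    fh.write("wavelength_nm,xbar,ybar,zbar\n")
    for w in wl5:
        x = np.interp(w, wl10, xbar10)
        y = np.interp(w, wl10, ybar10)
        z = np.interp(w, wl10, zbar10)
        fh.write(f"{w},{x:.6f},{y:.6f},{z:.6f}\n")

with open(out / "illuminant_d65_5nm.csv", "w") as fh:
    fh.write("wavelength_nm,d65\n")
    for w in wl5:
        s = np.interp(w, wl10, d65_10)
        fh.write(f"{w},{s:.4f}\n")

print("wrote", out)
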