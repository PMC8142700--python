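"""Regenerate the bundled sensor curve tables.

Writes two CSV tables into ``src/glavenstats/data``:

* ``cmf_cie1931_2deg.csv`` -- CIE 1931 2-degree color matching functions,
  evaluated from the multi-lobe Gaussian analytic fit of Wyman, Sloan &
  Shirley (JCGT 2013) on a 1 nm grid over 360-830 nm.
* ``cone_fundamentals_2deg.csv`` -- L/M/S sensitivity curves obtained by
  applying the Hunt-Pointer-Estevez cone transform to the CMFs.

Both files are plain text and user-replaceable; see glavenstats.colorspace.
"""

from pathlib import Path

import numpy as np

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "glavenstats" / "data"

# Hunt-Pointer-Estevez XYZ -> LMS transform.
HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)


def _lobe(wl, amp, mu, inv_sig_lo, inv_sig_hi):
    inv = np.where(wl < mu, inv_sig_lo, inv_sig_hi)
    return amp * np.exp(-0.5 * ((wl - mu) * inv) ** 2)


def cmfs_1931(wl):
    x = (
        _lobe(wl, 0.362, 442.0, 0.0624, 0.0374)
        + _lobe(wl, 1.056, 599.8, 0.0264, 0.0323)
        + _lobe(wl, -0.065, 501.1, 0.0490, 0.0382)
    )
    y = _lobe(wl, 0.821, 568.8, 0.0213, 0.0247) + _lobe(wl, 0.286, 530.9, 0.0613, 0.0322)
    z = _lobe(wl, 1.217, 437.0, 0.0845, 0.0278) + _lobe(wl, 0.681, 459.0, 0.0385, 0.0725)
    return np.column_stack([x, y, z])


def main():
    wl = np.arange(360.0, 831.0, 1.0)
    xyz = cmfs_1931(wl)

    lms = xyz @ HPE.T
    lms = np.clip(lms, 0.0, None)

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    header_cmf = "wavelength_nm,xbar,ybar,zbar"
    header_lms = "wavelength_nm,L,M,S"
    with open(DATA_DIR / "cmf_cie1931_2deg.csv", "w") as fh:
        fh.write(header_cmf + "\n")
        for w, row in zip(wl, xyz):
            fh.write(f"{w:.1f},{row[0]:.8f},{row[1]:.8f},{row[2]:.8f}\n")
    with open(DATA_DIR / "cone_fundamentals_2deg.csv", "w") as fh:
        fh.write(header_lms + "\n")
        for w, row in zip(wl, lms):
            fh.write(f"{w:.1f},{row[0]:.8f},{row[1]:.8f},{row[2]:.8f}\n")
    print("wrote tables to", DATA_DIR)


if __name__ == "__main__":
    main()
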