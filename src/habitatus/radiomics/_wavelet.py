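"""Single-level undecimated wavelet decomposition into eight bands.

The 2-D image is treated as a one-slice volume and decomposed with all
low/high-pass combinations along the three axes, giving bands
wavelet-LLL ... wavelet-HHH (letters ordered row, column, slice). In-plane
filtering is an undecimated separable convolution with the wavelet's
decomposition filters (mirror padding, so band images keep the input
shape). Along the length-one slice axis the signal is constant, so the
low-pass factor reduces to multiplication by sum(dec_lo) and the
high-pass factor to multiplication by sum(dec_hi) = 0: slice-high-pass
bands are identically zero, the analytic consequence of a single-slice
volume, and their features take constant-image values.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import convolve1d

BAND_NAMES = tuple(
    f"wavelet-{r}{c}{s}" for r in "LH" for c in "LH" for s in "LH"
)


def wavelet_bands(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Return the eight named band images of a 2-D input."""
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo)
    hi = np.asarray(wav.dec_hi)
    img = np.asarray(image, dtype=float)
    rows = {
        "L": convolve1d(img, lo, axis=0, mode="mirror"),
        "H": convolve1d(img, hi, axis=0, mode="mirror"),
    }
    plane = {}
    for r, rimg in rows.items():
        plane[r + "L"] = convolve1d(rimg, lo, axis=1, mode="mirror")
        plane[r + "H"] = convolve1d(rimg, hi, axis=1, mode="mirror")
    s_lo, s_hi = float(lo.sum()), float(hi.sum())
    out = {}
    for rc, pimg in plane.items():
        out[f"wavelet-{rc}L"] = pimg * s_lo
        out[f"wavelet-{rc}H"] = pimg * s_hi
    return out
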