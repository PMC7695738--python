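import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_lab(rgb):
    """Scalar closed-form CIE oracle: sRGB companding → XYZ → L*a*b*.

    Uses the 7-decimal IEC sRGB matrix with reference white = XYZ of sRGB
    white, matching the package's declared convention but implemented as an
    independent per-pixel scalar loop.
    """
    M = [[0.4124564, 0.3575761, 0.1804375],
         [0.2126729, 0.7151522, 0.0721750],
         [0.0193339, 0.1191920, 0.9503041]]
    white = [sum(row) for row in M]

    def eotf(s):
        return s / 12.92 if s <= 0.04045 else ((s + 0.055) / 1.055) ** 2.4

    def f(t):
        d = 6 / 29
        return t ** (1 / 3) if t > d**3 else t / (3 * d * d) + 4 / 29

    out = np.empty(rgb.shape)
    for i in range(rgb.shape[0]):
        for j in range(rgb.shape[1]):
            lin = [eotf(float(v)) for v in rgb[i, j]]
            xyz = [sum(M[r][c] * lin[c] for c in range(3)) for r in range(3)]
            fx, fy, fz = (f(xyz[k] / white[k]) for k in range(3))
            out[i, j] = (116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz))
    return out
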