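"""Small helper shared by CLI tests: write a closed-form sinc profile CSV."""

import numpy as np
import pandas as pd


def write_sinc_profile(path, lam=0.513333, z=60.0, d=28.16):
    x = np.arange(-4.0, 4.001, 0.01)
    amp = np.abs(np.sinc(d * x / (lam * z))) + 1e-12
    level = 20 * np.log10(amp / amp.max())
    pd.DataFrame({"x_mm": x, "amplitude_dB": level}).to_csv(path, index=False)
    return path
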