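"""Why the median multitaper combiner: resistance to transient artifacts.

A 20 s noise segment is corrupted by a single 0.1 s pulse ten times the
signal's SD.  The mean-combined spectrum absorbs the transient everywhere;
the ln2-corrected median barely moves.  Printed numbers are the mean
absolute log-distortion of the 1-45 Hz spectrum relative to the clean
segment — smaller is better.
"""

import numpy as np

from vreeg import EEGSegment, robust_multitaper_psd

rng = np.random.default_rng(0)
x = rng.standard_normal(2560)
dirty = x.copy()
width = 13
start = rng.integers(0, 2560 - width)
dirty[start : start + width] += 10 * x.std() * np.hanning(width)

for combiner in ("mean", "median"):
    clean_psd = robust_multitaper_psd(
        EEGSegment(data=x[None], fs=128, channel_labels=("Cz",)), combiner=combiner
    )
    dirty_psd = robust_multitaper_psd(
        EEGSegment(data=dirty[None], fs=128, channel_labels=("Cz",)), combiner=combiner
    )
    mask = (clean_psd.freqs >= 1) & (clean_psd.freqs <= 45)
    distortion = np.mean(np.abs(np.log(dirty_psd.power[0, mask] / clean_psd.power[0, mask])))
    print(f"{combiner:6s} combiner: log-spectral distortion from one transient = {distortion:.3f}")
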