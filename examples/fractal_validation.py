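"""Validate the Higuchi fractal-dimension estimator on known-dimension signals.

Weierstrass cosine sums and fractional Brownian motion with Hurst exponent H
have theoretical fractal dimension 2 - H; a straight line has dimension 1 and
white noise approaches 2.  The printed means should sit within a few
hundredths of those targets.
"""

import numpy as np

from vreeg import FractalSpec, gen_fractal_signal, higuchi_fd

for kind in ("weierstrass", "fbm"):
    for hurst in (0.3, 0.5, 0.7):
        fds = [
            higuchi_fd(gen_fractal_signal(FractalSpec(kind, 2048, hurst, seed=s)))
            for s in range(20)
        ]
        print(
            f"{kind:12s} H={hurst}: estimated FD {np.mean(fds):.3f} "
            f"(theory {2 - hurst:.1f}, sd {np.std(fds):.3f})"
        )

line_fd = higuchi_fd(gen_fractal_signal(FractalSpec("line", 2048)))
white_fd = np.mean(
    [higuchi_fd(gen_fractal_signal(FractalSpec("white", 4096, seed=s))) for s in range(20)]
)
print(f"straight line: FD {line_fd:.3f} (theory 1.0)")
print(f"white noise:   FD {white_fd:.3f} (theory 2.0)")
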