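"""Smooth a trace, detect local peaks, and build the inter-peak intervals.

The measurement chain: convolve with a unit-sum Gaussian (sigma = 1 sample,
i.e. 10 ms at 100 Hz) to suppress sharp high-frequency peaks, then mark
every sample strictly greater than both immediate neighbours, and
difference consecutive peak indices.
"""

import numpy as np

from ipidyn import (SleepState, compute_ipi, default_profiles, detect_peaks,
                    gaussian_smooth, generate_run)

profile = default_profiles()[SleepState.AWAKE]
run = generate_run(profile, n_ipi=1000, seed=3)

smoothed = gaussian_smooth(run.trace)
peaks = detect_peaks(smoothed)
ipi = compute_ipi(peaks, fs=run.trace.fs)

agreement = np.mean(ipi.intervals == run.true_ipi)
print(f"samples: {len(run.trace)}, peaks found: {len(peaks)}, "
      f"intervals: {len(ipi)} (unit {ipi.unit_ms:g} ms/sample)")
print(f"recovered intervals agree with ground truth on {agreement:.1%} of positions")

# Under default measurement noise (2 uV on 40 uV peaks), the smoothed chain
# recovers the placed intervals almost exactly; disagreements are single
# one-sample shifts where noise or unequal flanks nudge a local maximum.
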