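"""Thermal fluctuation statistics of a polarizability time series.

Synthetic frames jitter a carbon line with Gaussian coordinate noise and
random rigid rotations, emulating a molecule tumbling in solution.  The
orientation-invariant average polarizability barely moves (conformation
signal only), while the direction-resolved vector magnitudes swing strongly
(rotation signal), exactly the separation exploited when interpreting
single-molecule scattering traces.
"""

from polscat import (carbon_line, polarizability_series,
                     summarize_fluctuations, thermal_frames)

frames = thermal_frames(carbon_line(8, 2.0), n_frames=60, noise_sigma=0.05,
                        rotate=True, seed=7)
series = polarizability_series(frames, dt=0.05)  # 50 ps spacing, in ns
summary = summarize_fluctuations(series)

print(f"{'channel':<14} {'mean (A^3)':>11} {'range %':>9} {'std %':>7} "
      f"{'SEM %':>7}")
for name, s in summary.channels.items():
    print(f"{name:<14} {s.mean:11.2f} {s.percent_range:9.2f} "
          f"{s.percent_std:7.2f} {s.standard_error_percent:7.3f}")
print("\nThe x/y/z vector channels fluctuate ~10x more than the rotation-")
print("invariant average: tumbling dominates over thermal deformation.")
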