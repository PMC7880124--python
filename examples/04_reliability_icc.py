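"""Test-retest reliability of a retinal metric across examinations.

Simulates repeated fractal-dimension measurements of 190 children under the
study's visit mix (1/2/3 examinations) and estimates the one-way
random-effects intraclass correlation ICC(1,1): the share of measurement
variance attributable to true between-child differences.
"""

import numpy as np

import retivasc as rv
from retivasc.synth import default_repeat_study

iccs = [rv.icc_oneway(default_repeat_study(seed=s)).icc for s in range(20)]
print(f"ICC(1,1) of repeated fractal-dimension measurements, 20 replicates:")
print(f"  mean {np.mean(iccs):.3f}, range {min(iccs):.3f}-{max(iccs):.3f}")
print("  (configured world targets the published reliability band 0.72-0.88)")

# degenerate limits
perfect = rv.simulate_repeats(np.random.default_rng(0).normal(1.5, 0.034, 100),
                              within_sd=0.0, n_exams=np.full(100, 2), seed=1)
print(f"no examination noise -> ICC = {rv.icc_oneway(perfect).icc:.3f}")
pure_noise = rv.simulate_repeats(np.full(100, 1.5), within_sd=0.02,
                                 n_exams=np.full(100, 3), seed=2)
print(f"no between-child variance -> ICC = {rv.icc_oneway(pure_noise).icc:.3f}")
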