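"""Schedule a segmented-flow candidate screen and detect the slugs.

Slugs injected every 6.6 min into a plug flow reactor with a 135-min
residence time pipeline the reactions: 20 candidates finish within
270 min where sequential batches would finish 2 — a 10x productivity
gain.  A synthetic conductivity trace of the first six slugs is then
generated, detected back, and the residence-time statistics computed.
"""

import numpy as np

import ivtwin as iv
from ivtwin.synthetic import gen_trace

cfg = iv.ReactorConfig(tau_min=135.0, dt_min=6.6, horizon_min=270.0)
schedule = iv.build_schedule(cfg)
print(f"slugs produced in {cfg.horizon_min:.0f} min: {schedule.n_slugs}")
print(f"productivity factor vs sequential batches: "
      f"{iv.productivity_factor(cfg):g}")

# detect the first six slugs from a noisy synthetic conductivity trace
six = iv.build_schedule(cfg, n_requested=6)
trace, truth = gen_trace(six, noise_sd=0.5, seed=11)
detected = iv.detect_slugs(trace)
print(f"\ndetected {detected['count']} of {truth['n_slugs']} slugs; "
      f"injection spacing {detected['spacing_mean_min']:.2f} "
      f"+/- {detected['spacing_sd_min']:.2f} min")

# residence time from paired inlet/outlet events with pump jitter
rng = np.random.default_rng(11)
outlet = six.injection_times + cfg.tau_min + 0.6 * rng.standard_normal(6)
stats = iv.residence_stats(six.injection_times, outlet)
print(f"residence time {stats['residence_mean_min']:.1f} "
      f"+/- {stats['residence_sd_min']:.1f} min over {stats['n']} slugs")
print("spacing shift inlet->outlet "
      f"{stats['spacing_dev_mean_min']:.2f} +/- {stats['spacing_dev_sd_min']:.2f} min")
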