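"""Extract event ages from gradual traits: milestones, peaks, attainment.

Gradual measurements (body volume, behavioral frequencies, ossification
counts) have no intrinsic event age; these extractors date one so the
trait can enter the translating-time model as a time point.
"""

import numpy as np

import agealign as aa
from agealign.synthetic import GrowthSpec, gen_growth_series

# Percent-of-adult milestones from a sigmoidal growth fit ----------------
ages, values, spec = gen_growth_series(GrowthSpec(sigma=0.5, seed=1))
fit = aa.fit_growth(ages, values)
print(f"growth family: {fit.family}, asymptote {fit.asymptote:.1f}")
for pct in (50, 90, 100):
    print(f"  {pct:>3}% of adult size at {aa.milestone_age(fit, pct):6.0f} d")
# (100% uses the 99%-of-asymptote rule: sigmoids never attain the limit.)

# Peak age from a smoothing spline ---------------------------------------
rng = np.random.default_rng(2)
t = np.sort(rng.uniform(10, 60, 40))
births = np.exp(-((t - 28.0) ** 2) / 60.0) + rng.normal(0, 0.03, 40)
peak = aa.peak_age(t, births)
print(f"peak at age {peak.age:.1f} (truth 28.0, censored={peak.censored})")

# Attainment age for an integer count series -----------------------------
t = np.sort(rng.uniform(100, 6000, 50))
carpals = np.clip(np.round(8 * t / 4000.0), 0, 8)  # 8 ossified carpals as adult
age = aa.attainment_age(t, carpals, adult_value=8)
print(f"adult carpal count reached at {age:.0f} d ({age / 365.25:.1f} y)")
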