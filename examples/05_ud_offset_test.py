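"""The proportionality test: is detection probability proportional to
utilization density?

The simple model forces a unit exponent on UD through an offset,
log(UD); freeing that exponent and comparing likelihoods/AICc tests
whether cameras over- or under-sample space relative to telemetry-based
space use. The full candidate sets (isopleth and core effects, with and
without UD) are ranked for binary and count responses.
"""

from camtel.encounters import build_encounter_table
from camtel.inference import offset_consistency_check
from camtel.pipeline import (estimate_surfaces, run_homerange_analysis,
                             simulate_study)
from camtel.simulate import SimConfig

cfg = SimConfig(seed=7, n_females=12, n_males=6,
                extent=(0, 0, 14_000, 14_000), camera_jitter=200.0)
study = simulate_study(cfg)
surfaces = {}
for season in ("FallWinter", "Summer"):
    surfaces.update(estimate_surfaces(study.tracks, season))
table = build_encounter_table(study.tracks, surfaces, study.cameras,
                              study.detections, "homerange")

chk = offset_consistency_check(table)
print(f"free exponent on log(UD): {chk['beta_ud']:.3f} "
      f"(95% CI {chk['ci'][0]:.3f} to {chk['ci'][1]:.3f}; "
      f"covers 1: {chk['covers_one']})")
print(f"offset-model AICc {chk['aicc_offset']:.1f} vs "
      f"free-model AICc {chk['aicc_free']:.1f}")
print(f"likelihood identity gap at exponent 1: {chk['identity_gap']:.2e}")

res = run_homerange_analysis(table)
print("\nbinary cloglog GLMs (AICc):")
print(res["binary_glm"].head(4).round(3).to_string(index=False))
print(f"\ncount models: saturated-model dispersion {res['count_c_hat']:.2f}; "
      "quasi-Poisson QAICc:")
print(res["count_quasi"].head(4).round(3).to_string(index=False))
# The exponent's CI covering 1 and the offset model ranking at or near
# the top mean camera detections are proportional to telemetry space use
# -- the two data types are consistent. Models without log(UD) trail by
# many AICc units.
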