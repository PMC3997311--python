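"""Proximity analysis: does activity near a camera predict detection?

Binary GLMMs (random intercept per animal) relate detection to the
number of telemetry relocations within 250 m of each camera, with sex
and season effects; candidate models are ranked by AICc with Akaike
weights and conditional R^2.
"""

from camtel.encounters import build_encounter_table
from camtel.pipeline import run_proximity_analysis, simulate_study
from camtel.simulate import SimConfig

cfg = SimConfig(seed=7, n_females=12, n_males=6,
                extent=(0, 0, 14_000, 14_000), camera_jitter=200.0)
study = simulate_study(cfg)
table = build_encounter_table(study.tracks, None, study.cameras,
                              study.detections, "proximity")

res = run_proximity_analysis(table, radius=250)
print(res["selection"].head(5).round(3).to_string(index=False))

best = res["best"]
print(f"\nbest model: {best.spec.name}")
curves = res["curves"]
for sex in ("F", "M"):
    c = curves[(curves.Sex == sex) & (curves.Season == "FallWinter")]
    p0 = c.loc[c.NLocs250.idxmin(), "prob"]
    p5 = c.iloc[(c.NLocs250 - 5).abs().argsort().iloc[0]]["prob"]
    print(f"  {sex}, Fall/Winter: Pr(detect) {p0:.2f} at 0 relocations "
          f"-> {p5:.2f} at ~5")
# Detection probability rises steeply with nearby relocations -- the
# cameras are seeing the same space use the telemetry records.
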