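"""Parameter recovery: closing the loop on the simulator.

Replicates of simulate -> fit show that the free-exponent model recovers
the true exponent on utilization density without bias when the covariate
is the true density, and that information criteria prefer the offset
(proportional) model when proportionality actually generated the data.
"""

from camtel.pipeline import run_recovery_experiment
from camtel.simulate import SimConfig

cfg = SimConfig(seed=21, n_females=20, n_males=20,
                extent=(0, 0, 12_000, 12_000), camera_jitter=200.0,
                beta_ud=1.0)
rep = run_recovery_experiment(
    cfg, n_replicates=20, ud_source="true",
    n_cameras_extent=(1000, 3000, 11_000, 9000),
)
print(rep.params.round(3).to_string(index=False))
print("\ntop-model frequency:")
print(rep.top_models.round(2).to_string())
# Mean recovered exponent ~1 with near-nominal CI coverage; the offset
# (proportional) model wins the AICc comparison in most replicates, as
# it should when the simple model is the generating truth.
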