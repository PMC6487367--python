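"""Still stand and front-leg search movements.

Stops the walking model under the right-leg velocity constraint,
measures how fast the still-stand pose is reached, restarts, and then
demonstrates search movements of both front legs during walking.
"""
from hexawalk import experiments as ex

stop = ex.measure_stop()
print(f"stop accepted at t={stop['accept_time']:.0f} ms; complete "
      f"still-stand pose after {stop['stop_time_ms']:.0f} ms")
print(f"restart: first lifted leg(s) {stop['first_lifted']}, "
      f"emerging pattern: {stop['restart_label']}")

search = ex.measure_search()
for leg in search["legs"]:
    d = search[leg]
    print(f"search {leg}: alpha held at {d['alpha_hold']:.1f} deg, "
          f"beta at {d['beta_hold']:.1f} deg, tibia oscillating with "
          f"{d['gamma_period']:.0f} ms period")
print("walking-leg period ratios during search:",
      {k: round(v, 3) for k, v in search["walking_period_ratio"].items()})
print("pattern after search ends:", search["resumed_label"])
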