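"""Generate a calibrated switcher panel and reproduce the descriptive
table.

Builds a person-year panel at the generator's defaults (incomes ~47.4
thousand EUR/yr, ~16% sick years among switchers), keeps the switchers,
and prints per-state means: life satisfaction is ~0.3 points lower and
net income ~4% lower in sick years.
"""

import statedep as sd

cfg = sd.SyntheticConfig(seed=1)
panel = sd.simulate_panel(cfg)
switchers = sd.filter_switchers(panel)

table = sd.summarize_panel(switchers)
print(table.round(2).to_string(index=False))
print(f"\nindividuals: {table.attrs['n_individuals']}, "
      f"mean periods: {table.attrs['mean_periods']:.2f}, "
      f"of which sick: {table.attrs['mean_sick_periods']:.2f}")

ls = {r["state"]: r["mean"] for _, r in table.iterrows()
      if r["variable"] == "life_satisfaction"}
inc = {r["state"]: r["mean"] for _, r in table.iterrows()
       if r["variable"] == "net_income"}
print(f"healthy-sick LS gap: {ls['healthy'] - ls['sick']:.2f} points; "
      f"sick-year income shortfall: "
      f"{100 * (1 - inc['sick'] / inc['healthy']):.1f}%")
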