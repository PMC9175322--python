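"""Build an abridged life table and read off LE and lifespan inequality.

A Gompertz-Makeham hazard with an infant hump is evaluated on the
standard 19-group age ladder (0, 1-4, 5-9, ..., 85+), converted to a life
table, and summarised by life expectancy at birth (e0, the mean of the
age-at-death distribution) and lifespan inequality (its standard
deviation).
"""

import lifegap as lg

hazard = lg.HazardSpec()  # defaults: adult LE in the mid-70s
rm = lg.make_rates(hazard, country="DEMO", sex="male")
lt = lg.build_lifetable(rm.all_cause(), sex="male")

print(lt.round(5).to_string(index=False))
e0 = lg.life_expectancy(lt)
sd = lg.lifespan_sd(lt)
print(f"\nlife expectancy at birth e0 = {e0:.2f} years")
print(f"lifespan inequality (SD of age at death) = {sd:.2f} years")
print("\nA higher SD means greater uncertainty in the timing of death;")
print("saving lives at young ages lowers it, at old ages raises it.")
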