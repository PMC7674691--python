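"""Reference thyroid retention curves for the five intake routes.

Builds the ICRP compartment system for each route at the deterministic
reference parameter set, solves it by matrix exponentiation, and prints the
thyroid fraction of a 1 Bq acute I-131 intake at a few times.  The ingestion
curve peaks between one and two days — thyroid uptake is complete after
roughly a day, after which slow biological turnover and physical decay drive
the decline.
"""

import thyret as th

times = (2.0, 6.0, 24.0, 48.0, 168.0)

print(f"{'route':16s}" + "".join(f"  m({t:>5.0f} h)" for t in times))
for route in th.Route:
    curve = th.reference_retention(route)
    row = "".join(f"  {curve.interpolate(t):9.4f}" for t in times)
    print(f"{route.value:16s}{row}")
print("\nValues are Bq in thyroid per Bq intake; columns are hours since intake.")
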