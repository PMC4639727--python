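"""Analytic view: when does cooperation out-earn free-riding?

Within a single group a defector's receipts always dominate (it gets
every shared payment plus its private gains).  Between groups, an
all-cooperator group wins once its capacity lead over a defector-carrying
group exceeds a threshold; this prints that threshold across task
simplicities, for large groups and for lone players.
"""

from crowdsolve.meanfield import expected_individual_gain, meanfield_table

print(meanfield_table([0.1 * k for k in range(1, 11)], S=100)
      .to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

print(f"\nexpected private gain of a lone individualist at R=1: "
      f"{expected_individual_gain(1.0):.1f}")

# delta_large_S: capacity lead a 100-player cooperator group needs;
# delta_unit_S: capacity a lone cooperator needs before defection stops
# paying.  Both grow with R - easier tasks make free-riding more
# tempting, but easier tasks also build capacity faster, which balances.
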