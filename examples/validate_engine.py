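"""Certify the stochastic engine against closed-form expectations.

Replays many independent single iterations of random small-group
configurations through the engine and z-tests the Monte-Carlo means of
the capacity increment, shared gains, private gains, role counts and
gain draws against their exact values.
"""

from crowdsolve import ModelParams
from crowdsolve.validation import run_oracle_battery

params = ModelParams(N=10, S=10, R=0.5, seed=0)
reports = run_oracle_battery(params, n_configs=3, n_samples=20_000)

for rep in reports:
    print(rep)
print(f"\n{sum(r.passed for r in reports)}/{len(reports)} checks passed "
      "(|z| <= 3 means the engine agrees with the closed form)")
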