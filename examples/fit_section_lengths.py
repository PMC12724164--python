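"""Which right-skewed family generated these section lengths?

Six candidate families (Wald, log-normal, gamma, exponential, log-logistic,
minimum Weibull) are fitted by maximum likelihood and ranked by
BIC = k ln n - 2 loglik.  Lower BIC wins; the k ln n penalty keeps the
1-parameter exponential competitive against families that nest it.
"""

import numpy as np

from dendromorph import select

rng = np.random.default_rng(3)

samples = {
    "inter-branch intervals (planted minimum Weibull)": 1.3 * rng.weibull(1.6, 5000),
    "terminal tip lengths  (planted log-normal)": np.exp(rng.normal(0.0, 0.5, 5000)),
    "scaled inter-branch   (planted gamma)": rng.gamma(2.5, 0.52, 5000),
}

for label, x in samples.items():
    ranked = select(x)
    best, runner = ranked[0], ranked[1]
    print(f"{label}")
    print(f"  winner: {best.family}  params={ {k: round(v, 3) for k, v in best.params.items()} }")
    print(f"  BIC margin to runner-up ({runner.family}): "
          f"{runner.bic - best.bic:.1f}\n")

print("a BIC margin of ~10 is already decisive; the planted family should"
      "\nwin each time at this sample size.")
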