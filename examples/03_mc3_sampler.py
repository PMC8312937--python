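"""MC3 model-composition sampling versus exact enumeration.

The chain walks the model space by single add/remove moves (plus a
self-proposal), accepting with the posterior ratio. Visited models keep
their exact marginals, so the renormalized estimate converges much
faster than raw visit frequencies.
"""

import numpy as np

import voxelbma as vb

rng = np.random.default_rng(5)
n, k = 57, 5
X = rng.normal(size=(n, k))
y = 0.45 + 0.02 * X[:, 1] + rng.normal(0, 0.05, n)
prior = vb.default_g(n, k)

cfg = vb.MC3Config(n_iterations=50_000, burn_in=5_000, seed=5)
trace = vb.mc3_run(y, X, prior, cfg)
exact = vb.enumerate_models(y, X, prior)

freq = np.zeros(1 << k)
freq[trace.visited_masks] = trace.frequency_probs
renorm = np.zeros(1 << k)
renorm[trace.visited_masks] = trace.renormalized_probs

print(f"visited {len(trace.visited_masks)} of {1 << k} models; "
      f"accepted {trace.n_accepted}/{trace.n_iterations} proposals")
print("TV(frequency, exact)   :", round(0.5 * np.abs(freq - exact.posterior_probs).sum(), 4))
print("TV(renormalized, exact):", round(0.5 * np.abs(renorm - exact.posterior_probs).sum(), 6))

best = vb.best_model(trace)
print(f"best visited model mask: {best.mask:05b} (covariate 1 is bit 1; "
      "a total-variation distance below 0.05 means the chain has mixed)")
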