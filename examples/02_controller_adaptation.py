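"""The sequestration controller as an approximate differentiator.

Drives the isolated controller (X, U1, U2) with a slowly settling input and
compares the full dynamics against the fast-sequestration limit: a low-pass
cascade followed by a clipped derivative-like combination. At the design
point r = ξδ/(kθ) = 1 the output adapts perfectly — it returns to zero once
the input stops changing — and the approximation error shrinks as the
sequestration rate γ grows.
"""

import numpy as np

import fatebias as fb

params = fb.nominal_params()
print("adaptive metric r =", fb.adaptive_metric(params))

t = np.linspace(0, 30, 1201)
input_fn = lambda s: 2.0 * s * np.exp(-s / 3.0)   # pulse: rises, then decays

approx = fb.approx_output(params, input_fn, t)
print(f"approximate output: peak {approx.max():.4f} μM at "
      f"t = {t[approx.argmax()]:.1f} h, final {approx[-1]:.2e} μM")
print("The output fires only while the input *falls* (the delayed X→U1 path "
      "outruns the direct U2 path) and adapts back to zero afterwards.")

gammas = [1, 10, 100, 1000]
errors = fb.error_vs_gamma(params, input_fn, gammas, t)
print("\nsup-norm error of the full controller vs the fast-sequestration limit:")
for g, e in zip(gammas, errors):
    print(f"  gamma = {g:5d} /μM/h  ->  {e:.4f} μM")
print("The error falls monotonically with γ: faster sequestration makes the "
      "circuit a cleaner differentiator.")
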