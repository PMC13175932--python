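"""Identify the penicillin production equation from batch fermentations.

Twenty 100-hour batches are simulated with a Contois biomass/substrate
subsystem driving the product equation

    dx1/dt = mu_p * x2 * x4 / (Kp + x2 + x2^2/K1) - K * x1,

(x1 product, x2 substrate, x4 biomass; substrate inhibition in the
denominator).  A degree-3 library over (x1, x2, x4) has 40 columns; the
null space selects the 7 terms of the cleared-denominator identity.
"""

import warnings

import ratdyn

warnings.simplefilter("ignore", RuntimeWarning)

result = ratdyn.run_benchmark("penicillin", seed=0)

nv = result.null_vectors[0]
print(f"active terms: {len(nv.support)} of {result.library_sizes[0]} candidates")
print("identified equation:")
print(" ", result.rational_models[0].equation_string())
print("recovered parameters:", {k: f"{v:.10g}" for k, v in result.named_parameters.items()})
print(f"relative parameter error: {result.report.frobenius_error:.3g}")
# mu_p, Kp, K and the substrate-inhibition constant K1 are recovered from
# the data alone; only the product equation is identified (growth and
# substrate dynamics serve as exogenous excitation).
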