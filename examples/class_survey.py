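"""Random-network survey: how element count and state count shape the CES.

Draws small batches of random deterministic networks from three classes
(three binary nodes, two ternary nodes, three ternary nodes), evaluates
each at one state sampled from its TPM, and prints the mean number of
causal distinctions, mean Phi and mean small phi per class.  More
elements raise Phi but dilute the average distinction; more states per
element raise both.
"""

import mvphi as m

N = 40
for label in ("222", "33", "333"):
    df, s = m.run_class_survey(label, N, seed=11)
    print(
        f"class {label}: <#distinctions> = {s['n_distinctions_mean']:.2f} "
        f"(max {2 ** m.ClassLabel.parse(label).n - 1}), "
        f"<Phi> = {s['big_phi_mean']:.3f}, "
        f"<phi> = {s['mean_small_phi_mean']:.3f}   [n = {N}]"
    )
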