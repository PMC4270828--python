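"""Build hierarchy models and inspect their exact liability distributions.

The liability of a subject is the result of folding its six genotypes and
the environment value through the model's function chain; because every
input is a small discrete variable, the full liability distribution is
computed exactly, and the disease threshold is chosen on it.
"""

from epihier import HierarchyModel, LiabilityDistribution, liability_distribution

additive = HierarchyModel(functions=("ADD",) * 6)
parity = HierarchyModel(functions=("XOR", "XOR", "ADD", "ADD", "ADD", "ADD"))

for name, model in [("all-additive", additive), ("parity head (XOR, XOR)", parity)]:
    liab = LiabilityDistribution.from_model(model, target_prevalence=0.10)
    print(f"\n{name} model: functions = {model.functions}")
    print("exact liability distribution P(X = x):")
    for value, p in liab.dist.items():
        print(f"  x = {value:3d}   p = {p:.6f}")
    print(f"threshold t = {liab.threshold}: disease iff liability >= t")
    print(f"achieved prevalence P(X >= t) = {liab.achieved_prevalence:.4f} "
          "(closest attainable at or above the 0.10 target)")

# the two computation routes agree exactly
fold = liability_distribution(parity, method="fold")
enum = liability_distribution(parity, method="enumerate")
print(f"\nfold == enumeration over all 3,645 input combinations: "
      f"{fold.allclose(enum, tol=1e-12)}")
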