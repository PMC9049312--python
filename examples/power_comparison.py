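"""Power of ceCLC versus the omnibus quadratic form under group structure.

When the variant drives only one of two trait clusters (two-factor layout),
pooling statistics within clusters should beat the unstructured chi-square on
all traits. 400 replicates at N = 3000, K = 20, alpha = 0.05.
"""

from ceclc import ExperimentConfig, FactorModelSpec, run_power

spec = FactorModelSpec(model_id=2, K=20, N=3000, beta=0.03)
config = ExperimentConfig(
    spec=spec,
    n_replicates=400,
    alpha_levels=(0.05,),
    methods=("ceclc", "omnibus"),
    seed=9,
)
result = run_power(config)
for method in config.methods:
    print(f"power of {method:8s} at alpha=0.05: "
          f"{result.rate(method, 0.05):.3f}")
print("ceCLC pools the affected cluster's statistics, so it should reject"
      " more often than the omnibus form in this layout.")
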