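"""Export the decomposition for plotting: a range bar plot of AATEs.

Rows are ordered from the most vulnerable subgroup (highest AATE) to the
least; the ATE rides along as table metadata for the plot header.
"""

from causalrules import (
    GeneratorParams,
    PipelineConfig,
    cre_fit,
    export_plot_data,
    generate_dataset,
)

ds = generate_dataset(GeneratorParams(n=5000, n_rules=4, effect_size=5.0, seed=3))
result = cre_fit(ds.y, ds.z, ds.X, config=PipelineConfig(seed=3))

table = export_plot_data(result)
print(table.to_string(index=False))
print(f"\nATE (plot header): {table.attrs['ate']:+.4f}")

try:
    from causalrules import plot_decomposition

    ax = plot_decomposition(result)
    ax.figure.savefig("scratch_decomposition.png", bbox_inches="tight")
    print("saved range bar plot to scratch_decomposition.png")
except ImportError:
    print("matplotlib not installed; skipped rendering")
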