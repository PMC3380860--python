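"""Z-score over-representation of biological processes in the specific set.

Runs the full pipeline, then scores each gene-set category by the
hypergeometric standard score z = (k - mu) / sigma; a category is called
significant when z > 3.
"""

from specifex import pipeline

report = pipeline.run_all(pipeline.RunConfig(seed=42))
enr = report.enrichment_table
print(enr.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

# The two categories seeded with implanted specific genes (mRNA processing,
# mitochondrial metabolism) stand far above z = 3, the random categories do
# not — mirroring how RNA-processing categories dominate a real annotation.
print("\nsignificant categories:", enr.loc[enr.significant, "category"].tolist())
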