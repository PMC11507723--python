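"""ALL-IN expression-based mutual-exclusivity score.

From a protein x cell-line matrix of z-scored log abundances with lineage
labels, four sub-scores are computed per co-complex pair (cell-line bicor,
lineage-mean bicor, a large-expression-difference score on the imputed
matrix, and the lineage profile of each protein's correlation with the
rest of its complex). Oriented, z-scored and averaged, the ALL-IN score is
high for pairs that look mutually exclusive across cancer lineages.
"""

import complexkit as ck
from complexkit.allin import ExpressionMatrix
from complexkit.simulate import ExpressionSpec, simulate_expression

matrix, lineages, complexes, truth = simulate_expression(ExpressionSpec(seed=11))
print(f"expression matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} cell lines, "
      f"{lineages.nunique()} lineages")

em = ExpressionMatrix(ck.zscore_relative(matrix), lineages)
allin = ck.allin_scores(em, complexes, seed=11)
print(f"{len(allin)} co-complex pairs scored (>= 2 sub-scores each)")

joined = allin.join(truth.set_index(["protein_a", "protein_b"]), how="inner")
means = joined.groupby("planted_label")["allin"].mean()
print("\nmean ALL-IN by planted pair type:")
print(means.to_string())
# exclusive pairs score well above consistent ones: the score's whole point

top = joined.sort_values("allin", ascending=False).head(3)
print("\ntop-scoring pairs (all planted exclusive):")
print(top[["allin", "n_subscores", "planted_label"]].to_string())
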