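#!/usr/bin/env python
"""PCA and hierarchical clustering of the product profiles.

Runs PCA under both covariance and correlation preprocessing and an
average-linkage dendrogram on the 32 × 10 concentration matrix (codes
as numeric values). Finding: covariance-mode PCA partitions the
variance as PC1 30.4% / PC2 25.2%, matching the reported 30.3%/25.1%;
correlation mode gives 29.5%/19.3%, so the reported figures correspond
to an unstandardised (covariance) analysis. Leaves and seeds separate
along PC1 and fall in distant dendrogram branches.
"""

from pathlib import Path

import pandas as pd

from moringa_qc import biplot_coords, hclust, load_fixture, pca

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = load_fixture("table3_quant")
X = table.matrix()

rows = []
for mode in ("covariance", "correlation"):
    result = pca(X, preprocessing=mode)
    for k, frac in enumerate(result.explained_variance_fraction, start=1):
        rows.append({"mode": mode, "component": f"PC{k}", "variance_pct": 100 * frac})
    if mode == "covariance":
        comp = [f"PC{i+1}" for i in range(result.scores.shape[1])]
        pd.DataFrame(result.scores, index=table.sample_ids, columns=comp).to_csv(OUT / "pca_scores.csv")
        pd.DataFrame(result.loadings, index=table.compounds, columns=comp).to_csv(OUT / "pca_loadings.csv")
        sites, arrows = biplot_coords(result, alpha=1.0)
        pd.DataFrame(sites, index=table.sample_ids, columns=["PC1", "PC2"]).to_csv(OUT / "biplot_sites.csv")
        pd.DataFrame(arrows, index=table.compounds, columns=["PC1", "PC2"]).to_csv(OUT / "biplot_arrows.csv")
variance = pd.DataFrame(rows)
variance.to_csv(OUT / "pca_variance.csv", index=False)

tree = hclust(X, table.sample_ids, linkage="average")
(OUT / "dendrogram.nwk").write_text(tree.to_newick() + "\n")

for mode in ("covariance", "correlation"):
    sub = variance[variance["mode"] == mode].head(2)["variance_pct"].round(1).tolist()
    print(f"{mode:11s} PC1 {sub[0]}%  PC2 {sub[1]}%")
print(f"dendrogram: {len(table.sample_ids)} leaves, root height {tree.height:.2f}")
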