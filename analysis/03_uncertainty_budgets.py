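#!/usr/bin/env python
"""Top-down expanded uncertainty budgets per compound × matrix.

Builds the U₃/U₁₀ → U_c → U = 2·U_c chain from the published recovery
and inter-day RSD summaries at the bracketing 3 and 10 mg kg⁻¹ levels.
Finding: recomputed budgets are dominated by low-level recovery bias —
the largest sits at compound 1 in seeds (66.7% recovery at 3 mg kg⁻¹) —
while compounds with near-unit recovery carry budgets of a few percent.
The published expanded-uncertainty row itself is not recomputable from
the printed summaries (its defining formula is typographically corrupted
in print), so the recomputed budgets are reported side by side with the
published values rather than compared numerically.
"""

from pathlib import Path

from moringa_qc import load_fixture
from moringa_qc.uncertainty import budgets_from_validation

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

budgets = budgets_from_validation(load_fixture("table2_validation"))
published = load_fixture("table2_uncertainty").rename(columns={"u_expanded": "u_published"})
merged = budgets.merge(published, on=["compound", "medium"])
merged.to_csv(OUT / "uncertainty_budgets.csv", index=False)

worst = merged.loc[merged.u_expanded.idxmax()]
best = merged.loc[merged.u_expanded.idxmin()]
print(f"{len(merged)} budgets; U = 2·U_c throughout")
print(f"largest recomputed U: {worst.u_expanded:.1f}% (compound {worst.compound}, {worst.medium}; "
      f"published row prints {worst.u_published}%)")
print(f"smallest recomputed U: {best.u_expanded:.1f}% (compound {best.compound}, {best.medium}; "
      f"published row prints {best.u_published}%)")
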