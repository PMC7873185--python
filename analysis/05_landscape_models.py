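"""Relate functional structure to current and past landscapes; select by AICc.

For each taxon, species richness and the gated CWV/CWM responses are
regressed on the landscape predictors at each mapped year (full OLS: four
predictors for the plant groups, six for birds). Years within dAICc < 2 of
the minimum with normal residuals are selected; a past year selected over
the current one is the signature of a time-lagged response.
"""

from pathlib import Path

import pandas as pd

from traitscape.response import render_group_table, run_response_stage
from traitscape.synth import TAXA

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
YEARS = ("40_years_ago", "15_years_ago", "current")


def main() -> None:
    indices_all = pd.read_csv(RESULTS / "functional_indices.csv")
    indices = {t: indices_all[indices_all["group"] == t] for t in TAXA}
    gating = {t: pd.read_csv(RESULTS / f"gating_{t}.csv") for t in TAXA}
    lv = pd.read_csv(RESULTS / "landscape_variables.csv")

    results = run_response_stage(indices, gating, lv, YEARS)
    results.to_csv(RESULTS / "response_models.csv", index=False)
    for taxon in TAXA:
        if (results["group"] == taxon).any():
            wide = render_group_table(results, taxon)
            wide.to_csv(RESULTS / f"table_{taxon}.csv")

    sel = results[results["selected"]]
    print("selected model years per response (dAICc < 2, normal residuals):")
    for (group, resp), sub in sel.groupby(["group", "response"]):
        years = sorted(set(sub["year"]), key=YEARS.index)
        r2 = sub[sub["term"] == "r_squared"]["value"].max()
        print(f"  {group:<18} {resp:<24} {', '.join(years)}  (best R2 {r2:.2f})")
    unmodelled = results[results["term"] == "unmodelled"]
    for _, row in unmodelled.iterrows():
        print(f"  {row['group']:<18} {row['response']:<24} (no fit possible)")
    print(f"model tables -> {RESULTS}")


if __name__ == "__main__":
    main()
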