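"""Fit the propensity model and build baseline stabilised IPT weights.

Prints the weight diagnostics and the covariate balance before and after
weighting (the four-column descriptive layout), and writes weights.csv and
balance.csv under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from rtwstates.weighting import balance_table, compute_weights

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    cohort = pd.read_csv(OUT / "cohort.csv")
    weights, fit = compute_weights(cohort)
    weights.as_series().rename_axis("person_id").to_csv(OUT / "weights.csv")
    balance = balance_table(cohort, weights)
    balance.to_csv(OUT / "balance.csv", index=False)
    print(f"propensity model converged in {fit.n_iter} iterations")
    print("weight diagnostics:", {k: round(v, 3) for k, v in weights.diagnostics.items()})
    worst = balance.reindex(balance["smd_unweighted"].abs().sort_values().index[::-1])
    print("\nmost imbalanced confounder levels (SMD before -> after weighting):")
    for _, row in worst.head(6).iterrows():
        print(f"  {row['confounder']}={row['level']}: "
              f"{row['smd_unweighted']:+.3f} -> {row['smd_weighted']:+.3f}")


if __name__ == "__main__":
    main()
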