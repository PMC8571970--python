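#!/usr/bin/env python
"""Step 5 — does complexity track tooth replacement rate?

Pearson and Kendall correlations between OPCRavg and the replacement
interval (days), then the phylogenetic models: PGLS under Brownian-motion,
Pagel's-λ and Ornstein–Uhlenbeck correlation structures, and a
residual-randomization phylogenetic ANOVA, each per dataset scope
(complete assemblage, saurischian-analog and sauropod-analog subsets).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from toothkit.phylo import TraitVector, prune_to_common, read_newick
from toothkit.stats import (
    kendall_test,
    pearson_test,
    pgls_fit,
    phylo_anova,
)

SCOPES = {
    "all": None,
    "saurischian": {"theropod", "diplodocoid", "macronarian"},
    "sauropod": {"diplodocoid", "macronarian"},
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--project", type=Path,
                    default=Path("results/assemblage"))
    ap.add_argument("--summaries", type=Path,
                    default=Path("results/taxon_summaries.csv"))
    ap.add_argument("--iterations", type=int, default=9999)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=Path("results/rate_models.csv"))
    args = ap.parse_args()

    tree = read_newick(args.project / "tree.nwk")
    table = pd.read_csv(args.summaries)
    table = table.dropna(subset=["replacement_rate_days"])
    rows = []
    for scope, keep in SCOPES.items():
        sub = table if keep is None else table[table["clade"].isin(keep)]
        if len(sub) < 4:
            continue
        rate = sub["replacement_rate_days"].to_numpy(float)
        for threshold in (3, 5):
            y = sub[f"opcr_avg_{threshold}"].to_numpy(float)
            pr = pearson_test(rate, y)
            kd = kendall_test(rate, y)
            rows += [
                {"scope": scope, "threshold": threshold, "model": "pearson",
                 "estimate": pr.estimate, "stat": pr.statistic, "p": pr.p,
                 "n": pr.n},
                {"scope": scope, "threshold": threshold, "model": "kendall",
                 "estimate": kd.estimate, "stat": kd.statistic, "p": kd.p,
                 "n": kd.n},
            ]
            x_vec = TraitVector(rate, list(sub["taxon"]), units="days")
            ptree, x_aligned, _ = prune_to_common(tree, x_vec)
            y_map = dict(zip(sub["taxon"], y))
            y_aligned = TraitVector(
                np.array([y_map[t] for t in ptree.tip_labels]),
                ptree.tip_labels, units="PPT")
            for model in ("bm", "lambda", "ou"):
                fit = pgls_fit(ptree, y_aligned, x_aligned, model)
                rows.append({"scope": scope, "threshold": threshold,
                             "model": f"pgls_{model}", "estimate": fit.slope,
                             "stat": fit.t, "p": fit.p, "n": fit.n})
            an = phylo_anova(ptree, y_aligned, x_aligned,
                             iterations=args.iterations, seed=args.seed)
            rows.append({"scope": scope, "threshold": threshold,
                         "model": "phylo_anova", "estimate": an.F,
                         "stat": an.F, "p": an.p_perm,
                         "n": an.df_effect + an.df_resid + 1})
    out = pd.DataFrame(rows).round(4)
    out.to_csv(args.out, index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
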