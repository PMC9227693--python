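#!/usr/bin/env python
"""Train the synergy classifiers and rank candidate sensitizers.

On the RWR predictor matrix of 04_network_rwr.py: stratified 80/20 split,
10-fold cross-validated tuning of a random forest (bagged trees) and a
gradient-boosted tree model, held-out accuracy for both, and a ranking of
candidate sensitizing agents for one backbone drug, flagging candidates
supported by both model families.
"""

from pathlib import Path

import numpy as np

from metabarcode.prediction import (
    ClassifierSpec,
    encode_labels,
    holdout_accuracy,
    rank_sensitizers,
    split_train_test,
    tune_and_fit,
)
from metabarcode.synthetic import NetworkPlan, SynergyPlan, gen_combinations, gen_network

SEED = 1
BACKBONE = "D001"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    gen = gen_network(NetworkPlan(seed=SEED))
    combo = gen_combinations(SynergyPlan(seed=SEED), gen.net)
    X = combo.features.loc[[r.pair_id for r in combo.records]]
    y = encode_labels([r.label for r in combo.records])
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=SEED)
    print(f"train/test: {len(X_tr)}/{len(X_te)}")

    fits = {}
    for family in ("bagged-trees", "boosted-trees"):
        fit = tune_and_fit(X_tr, y_tr, ClassifierSpec(family=family, seed=SEED))
        fits[family] = fit
        acc = holdout_accuracy(fit, X_te, y_te)
        fit.cv_table.to_csv(RESULTS / f"cv_{family}.tsv", sep="\t", index=False)
        print(
            f"{family}: best {fit.best_params}, CV error {fit.cv_error:.3f}, "
            f"test accuracy {acc:.3f}"
        )

    candidates = sorted(d for d in combo.drug_targets if d != BACKBONE)
    ranking = rank_sensitizers(
        fits, BACKBONE, candidates, combo.drug_targets, gen.net
    )
    ranking.to_csv(RESULTS / "ranking.tsv", sep="\t", index=False)
    top = ranking.head(5)
    both = ranking[ranking["supported_by_both"]]["candidate"].tolist()
    print(f"\ntop candidates for backbone {BACKBONE}:")
    print(top.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"supported by both families (top-10 of each): {', '.join(both)}")


if __name__ == "__main__":
    main()
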