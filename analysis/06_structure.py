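#!/usr/bin/env python
"""Feature-structure analyses of the default cohort.

Per-feature cross-version agreement (overall and by age decade), per-feature
age correlations, permutation feature importance of single-version linear
models, the importance-by-measure exploratory correlation, and the PCA
variance / loading-composition summaries for both versions.
"""

import argparse
from pathlib import Path

from brainmix import cohort, structure
from brainmix.models import ModelSpec, fit_model
from brainmix.synthdata import GeneratorConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--repeats", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results/06_structure"))
    args = ap.parse_args()

    dataset, _ = generate_cohort(GeneratorConfig(n_participants=args.n, seed=args.seed))
    correlations = structure.cross_version_correlations(
        dataset, age_bins=structure.DEFAULT_AGE_BINS
    )
    age_corrs = {v: structure.age_correlations(dataset, v) for v in ("v5", "v7")}

    plan = cohort.make_split(dataset.participant_ids, seed=args.seed + 1)
    rankings = {}
    for version in ("v5", "v7"):
        plan_v = cohort.assign_versions(plan, f"single_{version}")
        Xtr, ytr, _ = cohort.assemble_design_matrix(dataset, plan_v, "train")
        model = fit_model(ModelSpec("linear", seed=args.seed), Xtr, ytr)
        rankings[version] = structure.permutation_importance(
            model, Xtr, ytr, n_repeats=args.repeats, seed=args.seed + 2
        )
    pca = structure.pca_by_feature_type(dataset)
    structure.write_structure_tables(
        args.out, correlations=correlations, age_corrs=age_corrs,
        rankings=rankings, pca=pca,
    )
    structure.importance_by_measure(rankings["v5"], dataset).to_csv(
        args.out / "importance_by_measure_v5.csv", index=False
    )
    overlap = set(rankings["v5"].top(10)) & set(rankings["v7"].top(10))
    print(f"top-10 importance overlap between versions: {len(overlap)}/10")
    for v, s in pca.items():
        print(f"{v} PCA variance explained (first 3): "
              f"{[round(x, 3) for x in s.variance_explained[:3]]}")


if __name__ == "__main__":
    main()
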