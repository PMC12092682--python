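#!/usr/bin/env python
"""Differential somatic mutation between ancestry groups, both routes.

Per-gene logistic models (mutated ~ ancestry + age, EUR reference, BH
adjustment, significant at adjusted p < 0.1) for estimable genes, the
strict >2% presence threshold classifier with its seven intersection
sets for the rest, and per-patient substitution-rate comparisons
against EUR.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bcancestry import io as bcio, somatic as som


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--feature-kind", choices=["gene", "variant"], default="gene")
    ap.add_argument("--outdir", default=str(Path(__file__).resolve().parents[1] / "results"))
    args = ap.parse_args()
    outdir = Path(args.outdir)

    clinical = bcio.read_clinical(str(outdir / "data" / "clinical.tsv"))
    classified = bcio.read_somatic_tsv(str(outdir / "somatic_fates.tsv"))
    analytic = clinical[clinical["gAncestry"].isin(som.ANALYTIC_GROUPS)]
    anc = analytic.set_index("participant_id")["gAncestry"]
    age = analytic.set_index("participant_id")["age_at_diagnosis"]

    matrix = som.build_mutation_matrix(classified, analytic["participant_id"],
                                       feature_kind=args.feature_kind)
    print(f"mutation matrix: {matrix.shape[0]} participants x {matrix.shape[1]} "
          f"{args.feature_kind}s")

    logi = som.per_feature_logistic(matrix, anc, age)
    logi.to_csv(outdir / "somatic_diff.tsv", sep="\t", index=False)
    sig = logi[logi["significant"]]
    print(f"logistic route: {int(logi['converged'].sum())} estimable terms, "
          f"{len(sig)} significant at adjusted p < 0.1")
    for _, row in sig.nsmallest(5, "p_adj").iterrows():
        print(f"  {row['feature']} ({row['term']} vs EUR): OR {row['odds_ratio']:.2f} "
              f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] adj p={row['p_adj']:.3g}")

    thr = som.threshold_classifier(matrix, anc)
    thr.to_csv(outdir / "somatic_threshold.tsv", sep="\t", index=False)
    sets = som.intersection_sets(thr)
    with open(outdir / "intersections.json", "w") as fh:
        json.dump(sets, fh, indent=1)
    print("threshold route intersection sizes "
          f"(minimal counts {thr.attrs['min_counts']}):")
    for k, v in sets.items():
        print(f"  {k}: {len(v)}")
    print(f"headline AFR-only {args.feature_kind}s: {sets['AFR'][:8]}")

    counts = (
        classified.groupby("sample_id").size()
        .reindex(analytic["participant_id"], fill_value=0)
        .rename("substitutions").to_frame()
    )
    rates = som.variant_class_rates(counts, anc, classes=("substitutions",))
    rates.to_csv(outdir / "variant_class_rates.tsv", sep="\t", index=False)
    print("per-patient substitution rates:")
    print(rates.to_string(index=False))


if __name__ == "__main__":
    main()
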