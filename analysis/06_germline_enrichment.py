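#!/usr/bin/env python
"""Germline pathogenicity filtering, burden and per-gene enrichment.

Calls are filtered to the 180-gene panel and canonical transcript, kept
as confident-pathogenic (ClinVar pathogenic/likely pathogenic at >= 2
stars) or VUS, summarised per ancestry group, and per-gene carrier
status is fitted with carrier ~ ancestry (EUR reference).  Also runs
the germline-BRCA-by-ER Fisher test on the clinical table.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bcancestry import germline as germ, io as bcio


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default=str(Path(__file__).resolve().parents[1] / "results"))
    args = ap.parse_args()
    outdir = Path(args.outdir)

    clinical = bcio.read_clinical(str(outdir / "data" / "clinical.tsv"))
    calls = bcio.read_germline(str(outdir / "data" / "germline.tsv"))
    panel = set(bcio.read_panel(str(outdir / "data" / "panel.txt")))

    classified = germ.classify_calls(calls, panel=panel)
    print(classified["fate"].value_counts().to_string())

    analytic = clinical[clinical["gAncestry"].isin(("EUR", "AFR", "SAS"))]
    groups = dict(zip(analytic["participant_id"], analytic["gAncestry"]))
    burden = germ.burden_summary(classified[classified["participant_id"].isin(groups)], groups)
    burden.to_csv(outdir / "germline_burden.tsv", sep="\t", index=False)
    print("per-participant burden by ancestry:")
    print(burden.to_string(index=False))

    carriers = germ.carrier_matrix(classified, list(analytic["participant_id"]))
    seen = carriers.columns[carriers.sum() > 2]
    factor = analytic.set_index("participant_id")["gAncestry"]
    enrich = germ.gene_enrichment(carriers[seen], factor)
    enrich.to_csv(outdir / "germline_enrichment.tsv", sep="\t", index=False)
    top = enrich[enrich["converged"]].nsmallest(6, "p_adj")
    print("strongest per-gene enrichment signals:")
    for _, row in top.iterrows():
        print(f"  {row['gene']} ({row['term']} vs EUR): OR {row['odds_ratio']:.2f} "
              f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] adj p={row['p_adj']:.3g}")

    sub = clinical.dropna(subset=["ER"])
    a = int(((sub["ER"] == "negative") & (sub["germline_brca"] == 1)).sum())
    b = int(((sub["ER"] == "negative") & (sub["germline_brca"] == 0)).sum())
    c = int(((sub["ER"] == "positive") & (sub["germline_brca"] == 1)).sum())
    d = int(((sub["ER"] == "positive") & (sub["germline_brca"] == 0)).sum())
    p, orr = germ.fisher_2x2(a, b, c, d)
    print(f"germline BRCA by ER: {a}/{a+b} ER- vs {c}/{c+d} ER+ carriers, "
          f"Fisher p = {p:.4f} (OR {orr:.2f})")
    with open(outdir / "brca_by_er.json", "w") as fh:
        json.dump({"table": [[a, b], [c, d]], "p": p, "odds_ratio": orr}, fh, indent=1)


if __name__ == "__main__":
    main()
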