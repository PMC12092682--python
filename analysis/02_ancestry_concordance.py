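#!/usr/bin/env python
"""Assign gAncestry labels (>= 0.8 proportion rule) and compare them with
self-reported ethnicity.

Reads results/data/clinical.tsv, re-derives the labels from the raw
ancestry proportions, and reports the concordance fraction with the
self-reported categories plus the full contingency table.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bcancestry import io as bcio
from bcancestry.ancestry import assign_labels, concordance


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default=str(Path(__file__).resolve().parents[1] / "results"))
    args = ap.parse_args()
    outdir = Path(args.outdir)

    clinical = bcio.read_clinical(str(outdir / "data" / "clinical.tsv"))
    labels = assign_labels(clinical)
    frac, table = concordance(labels, clinical["sre"])

    print(f"participants: {len(clinical)}")
    print(f"SRE/gAncestry concordance: {100 * frac:.1f}%")
    print(table.to_string())

    with open(outdir / "concordance.json", "w") as fh:
        json.dump({"concordance": frac, "table": table.to_dict()}, fh, indent=1)
    print(f"wrote {outdir / 'concordance.json'}")


if __name__ == "__main__":
    main()
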