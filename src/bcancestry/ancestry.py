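"""Genetic-ancestry (gAncestry) assignment and self-report concordance.

Participants carry a vector of superpopulation proportions (AFR, EUR,
EAS, SAS, AMR) estimated upstream from germline genotypes.  A
participant is assigned the superpopulation whose proportion reaches
the threshold (default >= 0.8, inclusive); anyone without a qualifying
component is labelled ``Admix``.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from bcancestry.config import SUPERPOPS

ADMIX = "Admix"

#: Default mapping from self-reported ethnicity categories to
#: superpopulation labels.  The mapping is deliberately coarse: health
#: records do not distinguish the five genetic superpopulations.
DEFAULT_SRE_MAPPING: Dict[str, str] = {
    "White": "EUR",
    "Black or Black British": "AFR",
    "Asian or Asian British": "SAS",
    "Mixed": ADMIX,
}

_SUM_TOL = 1e-6


class AmbiguousAncestryError(ValueError):
    """Two proportions tie exactly at the threshold (requires threshold <= 0.5)."""


def _validate_proportions(proportions: Mapping[str, float]) -> None:
    unknown = set(proportions) - set(SUPERPOPS)
    if unknown:
        raise ValueError(f"unknown superpopulation labels: {sorted(unknown)}")
    vals = list(proportions.values())
    if any(v < -_SUM_TOL or v > 1 + _SUM_TOL for v in vals):
        raise ValueError("ancestry proportions must lie in [0, 1]")
    total = sum(vals)
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"ancestry proportions sum to {total}, expected 1 +/- {_SUM_TOL}")


def assign_superpopulation(
    proportions: Mapping[str, float], threshold: float = 0.8
) -> str:
    """Return the gAncestry label for one participant.

    The unique superpopulation with proportion >= ``threshold``
    (inclusive comparison) wins; otherwise the participant is
    ``Admix``.  With a threshold above 0.5 and proportions summing to
    one at most a single component can qualify, but an exact tie at
    the threshold is guarded and raises rather than tie-breaking
    silently.
    """
    _validate_proportions(proportions)
    winners = [pop for pop, frac in proportions.items() if frac >= threshold]
    if len(winners) > 1:
        raise AmbiguousAncestryError(
            f"proportions {dict(proportions)} reach threshold {threshold} for {winners}"
        )
    return winners[0] if winners else ADMIX


def assign_labels(
    proportions: pd.DataFrame, threshold: float = 0.8, prefix: str = "prop_"
) -> pd.Series:
    """Vectorised assignment over a table of proportion columns.

    ``proportions`` must contain one ``{prefix}{POP}`` column per
    superpopulation present; rows must sum to one.
    """
    cols = [c for c in proportions.columns if c.startswith(prefix)]
    pops = [c[len(prefix):] for c in cols]
    unknown = set(pops) - set(SUPERPOPS)
    if unknown:
        raise ValueError(f"unknown superpopulation labels: {sorted(unknown)}")
    mat = proportions[cols].to_numpy(dtype=float)
    sums = mat.sum(axis=1)
    bad = np.abs(sums - 1.0) > _SUM_TOL
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} rows have ancestry proportions not summing to 1"
        )
    qualifies = mat >= threshold
    n_qual = qualifies.sum(axis=1)
    if (n_qual > 1).any():
        raise AmbiguousAncestryError("multiple proportions reach the threshold in some rows")
    labels = np.where(n_qual == 1, np.array(pops)[qualifies.argmax(axis=1)], ADMIX)
    return pd.Series(labels, index=proportions.index, name="gAncestry")


def concordance(
    labels: Sequence[str],
    sre: Sequence[Optional[str]],
    mapping: Optional[Mapping[str, str]] = None,
    include_missing: bool = False,
) -> Tuple[float, pd.DataFrame]:
    """Concordance between gAncestry labels and self-reported ethnicity.

    Returns the fraction of participants whose mapped self-report
    agrees with their genetic label, plus the full contingency table
    (rows: gAncestry label, columns: self-reported category).
    Participants with a missing self-report are excluded from the
    denominator unless ``include_missing`` (in which case they count
    as discordant).
    """
    if mapping is None:
        mapping = DEFAULT_SRE_MAPPING
    labels = list(labels)
    sre = list(sre)
    if len(labels) != len(sre):
        raise ValueError(f"{len(labels)} labels vs {len(sre)} self-reports")
    if not labels:
        raise ValueError("empty input: concordance is undefined for zero participants")

    def is_missing(x: object) -> bool:
        return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""

    observed = {s for s in sre if not is_missing(s)}
    unmapped = observed - set(mapping)
    if unmapped:
        raise ValueError(f"self-reported categories without a mapping: {sorted(unmapped)}")

    matches = 0
    denom = 0
    pairs = []
    for lab, s in zip(labels, sre):
        if is_missing(s):
            if include_missing:
                denom += 1
            pairs.append((lab, "<missing>"))
            continue
        denom += 1
        if mapping[s] == lab:
            matches += 1
        pairs.append((lab, s))
    if denom == 0:
        raise ValueError("no participants with a usable self-report")
    table = (
        pd.DataFrame(pairs, columns=["gAncestry", "sre"])
        .value_counts()
        .unstack(fill_value=0)
    )
    return matches / denom, table
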