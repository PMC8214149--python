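"""Weighted amino-acid preference statistic for diazirine labeling.

Carbene insertion is nonspecific, so the labeled site is often localized
only to an ambiguity set of n candidate positions.  To avoid
overcounting, each ambiguous site x contributes a weighted score
Wx = a_x,r / n, where a_x,r is the reagent's prior preference for the
residue at x (1 by default).  Summing over the m occurrences of residue
type x gives Wx' and normalizing gives the insertion likelihood
Px = Wx' / sum_k Wk', which sums to 1 over residue types.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "weighted_occurrence",
    "localization_precision",
    "sites_from_linkage",
]


def sites_from_linkage(sequence: str, positions: Sequence[int]) -> list[str]:
    """Residue letters of an ambiguity set within the diazirine-side peptide."""
    return [sequence[p - 1] for p in positions]


def weighted_occurrence(
    ambiguity_sets: Iterable[Sequence[str]],
    priors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue Wx' and Px from diazirine-side ambiguity sets.

    Each element of ``ambiguity_sets`` is the list of candidate residue
    letters (length n) for one identified cross-linked peptide.  With all
    priors equal to 1, each site contributes 1/n.  Returns a DataFrame
    indexed by residue with columns ``Wx_prime`` and ``Px``; Px sums to 1.
    """
    w: dict[str, float] = {}
    n_peptides = 0
    for sites in ambiguity_sets:
        sites = list(sites)
        if not sites:
            continue
        n_peptides += 1
        n = len(sites)
        for r in sites:
            a = 1.0 if priors is None else float(priors.get(r, 1.0))
            w[r] = w.get(r, 0.0) + a / n
    if n_peptides == 0:
        raise ValueError("no ambiguity sets supplied")
    total = sum(w.values())
    df = pd.DataFrame({
        "Wx_prime": pd.Series(w),
        "Px": pd.Series({r: v / total for r, v in w.items()}),
    }).sort_values("Px", ascending=False)
    df.index.name = "residue"
    return df


def localization_precision(
    ambiguity_sizes: Iterable[int],
) -> dict[str, float | bool]:
    """Fraction of identifications localized to 1, 2, 3 or >=4 sites."""
    sizes = list(ambiguity_sizes)
    bins = {"1": 0, "2": 0, "3": 0, "4+": 0}
    for n in sizes:
        if n < 1:
            raise ValueError("ambiguity size must be >= 1")
        bins["4+" if n >= 4 else str(n)] += 1
    total = len(sizes)
    out: dict[str, float | bool] = {
        k: (v / total if total else 0.0) for k, v in bins.items()}
    out["empty"] = total == 0
    return out
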