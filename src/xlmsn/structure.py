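"""Structural validation of cross-links against Calpha coordinates.

Residue linkages are mapped onto one or more structure models (e.g. the
four conformational states of the 26S proteasome), Calpha-Calpha
Euclidean distances are measured, satisfaction rates computed at the
linker-specific threshold (<=35 A for the long linker, <=30 A otherwise),
state-specific linkages classified into the 2^n - 2 proper satisfied
subsets (14 for four models), and the observed distances compared with a
Euclidean random-distance null (every K -> X pair under a distance cap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .assemble import ResidueLinkage
from .chem import CrosslinkerSpec

__all__ = [
    "StructureModel",
    "DistanceResult",
    "read_structure",
    "ca_distance",
    "satisfaction",
    "state_classify",
    "random_null",
    "null_histogram",
    "compare_to_null",
]


@dataclass
class StructureModel:
    """Calpha coordinates of one model, keyed by (chain, residue number)."""

    model_id: str
    coords: dict[tuple[str, int], np.ndarray]
    res_names: dict[tuple[str, int], str]
    chain_map: Mapping[str, str] | None = None  # subunit/accession -> chain

    def resolve(self, protein: str, residue: int) -> np.ndarray | None:
        chain = protein
        if self.chain_map is not None:
            chain = self.chain_map.get(protein, protein)
        return self.coords.get((chain, residue))


def read_structure(
    path: str | Path,
    chain_map: Mapping[str, str] | None = None,
    model_names: Sequence[str] | None = None,
) -> list[StructureModel]:
    """Read a (possibly multi-MODEL) PDB/mmCIF file at Calpha level."""
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    out: list[StructureModel] = []
    for mi, model in enumerate(st):
        coords: dict[tuple[str, int], np.ndarray] = {}
        names: dict[tuple[str, int], str] = {}
        for chain in model:
            for res in chain:
                ca = res.find_atom("CA", "*")
                if ca is None:
                    continue
                key = (chain.name, res.seqid.num)
                coords[key] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                names[key] = res.name
        if not coords:
            raise ValueError(f"model {mi + 1} of {path} has no CA atoms")
        mid = (model_names[mi] if model_names is not None
               else f"m{mi + 1}")
        out.append(StructureModel(mid, coords, names, chain_map))
    return out


def structures_from_gemmi(
    st, chain_map: Mapping[str, str] | None = None,
    model_names: Sequence[str] | None = None,
) -> list[StructureModel]:
    """Same as :func:`read_structure` but from an in-memory gemmi Structure."""
    import tempfile, os

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
        path = fh.name
    try:
        st.write_pdb(path)
        return read_structure(path, chain_map, model_names)
    finally:
        os.unlink(path)


def ca_distance(
    model: StructureModel,
    site_a: tuple[str, int],
    site_b: tuple[str, int | Sequence[int]],
) -> float | None:
    """Euclidean Calpha distance in Angstrom; None when unresolved.

    An ambiguity interval on the second site takes the minimum distance
    over its residues (the most permissive reading).
    """
    a = model.resolve(*site_a)
    if a is None:
        return None
    prot_b, res_b = site_b
    residues = res_b if isinstance(res_b, (list, tuple)) else (res_b,)
    best: float | None = None
    for r in residues:
        b = model.resolve(prot_b, r)
        if b is None:
            continue
        d = float(np.linalg.norm(a - b))
        if best is None or d < best:
            best = d
    return best


@dataclass
class DistanceResult:
    linkage: ResidueLinkage
    distances: dict[str, float | None]  # model id -> A (None = unresolved)
    satisfied: dict[str, bool]  # only models where the distance resolved
    category: str | None = None  # state-specific label, filled by classify

    @property
    def satisfied_set(self) -> frozenset[str]:
        return frozenset(m for m, s in self.satisfied.items() if s)


def satisfaction(
    linkages: Sequence[ResidueLinkage],
    models: Sequence[StructureModel],
    linker: CrosslinkerSpec,
) -> tuple[dict[str, float], list[DistanceResult]]:
    """Per-model distance satisfaction rates at the linker threshold.

    satisfied <=> distance <= max_ca_ca (boundary counts as satisfied).
    Unresolved linkages are excluded from a model's denominator.
    """
    if not models:
        raise ValueError("need >= 1 structure model")
    results: list[DistanceResult] = []
    for lk in linkages:
        dists: dict[str, float | None] = {}
        sat: dict[str, bool] = {}
        for m in models:
            d = ca_distance(m, (lk.protein_a, lk.res_a),
                            (lk.protein_b, lk.res_b))
            dists[m.model_id] = d
            if d is not None:
                sat[m.model_id] = d <= linker.max_ca_ca
        results.append(DistanceResult(lk, dists, sat))
    rates: dict[str, float] = {}
    for m in models:
        resolved = [r for r in results if r.distances[m.model_id] is not None]
        if not resolved:
            continue
        rates[m.model_id] = (sum(r.satisfied[m.model_id] for r in resolved)
                             / len(resolved))
    if not rates:
        raise ValueError("no linkage resolved in any model")
    return rates, results


def state_classify(
    results: Sequence[DistanceResult],
    model_ids: Sequence[str],
) -> dict[str, int]:
    """Count state-specific linkages over the proper satisfied subsets.

    Linkages satisfied by all models or by none are excluded; the rest go
    to the category named by their exact satisfied subset (joined with
    '-'), e.g. ``s1-s2-s3`` or ``s4``.  Four models give the canonical
    4 + 6 + 4 = 14 categories; other model counts generalize to
    2^n - 2 with a warning.
    """
    n = len(model_ids)
    if n != 4:
        warnings.warn(
            f"{n} models: generalizing to 2^{n} - 2 state categories",
            stacklevel=2)
    counts: dict[str, int] = {}
    for size in range(1, n):
        for combo in combinations(model_ids, size):
            counts["-".join(combo)] = 0
    for r in results:
        sat = [m for m in model_ids if r.satisfied.get(m)]
        if len(sat) == 0 or len(sat) == n:
            r.category = None
            continue
        label = "-".join(sat)
        r.category = label
        counts[label] += 1
    return counts


def random_null(
    model: StructureModel,
    cap: float,
    k_sites: Sequence[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Euclidean K -> X distance multiset under a distance cap.

    For every lysine Calpha (or explicitly supplied K sites) the distance
    to every other residue's Calpha is computed and kept when <= cap.
    This is the random-linkage background the observed distances are
    tested against (solvent-path distances deliberately skipped).
    """
    keys = list(model.coords)
    xyz = np.array([model.coords[k] for k in keys])
    if k_sites is None:
        k_idx = [i for i, k in enumerate(keys)
                 if model.res_names.get(k) == "LYS"]
    else:
        wanted = set(k_sites)
        k_idx = [i for i, k in enumerate(keys) if k in wanted]
    if not k_idx:
        raise ValueError("no lysine residues in model")
    dmat = np.linalg.norm(xyz[k_idx][:, None, :] - xyz[None, :, :], axis=2)
    mask = np.ones_like(dmat, dtype=bool)
    for row, i in enumerate(k_idx):
        mask[row, i] = False  # exclude self-pairing
    d = dmat[mask]
    return d[d <= cap]


def null_histogram(
    distances: np.ndarray, bin_width: float = 5.0
) -> pd.DataFrame:
    """Histogram of a distance multiset with fixed-width bins."""
    if distances.size == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    top = float(np.ceil(distances.max() / bin_width) * bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})


def compare_to_null(
    observed: np.ndarray, null: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: observed vs random distances."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = ks_2samp(observed, null)
    return float(stat), float(p)
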