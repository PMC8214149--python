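"""Integration of MS^n evidence into cross-link identifications.

MS3 PSMs are joined to their parent MS2 scans through the recorded scan
lineage, classified by remnant content into interlinks, dead-ends and
intralinks (with the +-20 ppm precursor reconstruction check the
cleavable-linker chemistry guarantees), filtered by target-decoy FDR,
then collapsed to unique peptide-pair sequences and protein-coordinate
K-X residue linkages for structural mapping and preference statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import CrosslinkerSpec, WATER, neutral_from_mz
from .search import PSM, SearchResult, SignaturePair, Tolerances

__all__ = [
    "CrosslinkID",
    "ResidueLinkage",
    "assemble",
    "fdr_filter",
    "collapse",
    "CollapseResult",
    "replicate_overlap",
    "ids_to_tsv",
    "linkages_to_tsv",
    "linkages_to_xinet_csv",
]


@dataclass
class CrosslinkID:
    kind: str  # interlink | deadend | intralink
    ms2_scan: int
    linker: str
    alpha: PSM
    beta: PSM | None
    ppm_error: float
    score: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if self.kind not in ("interlink", "deadend", "intralink"):
            raise ValueError(f"unknown kind {self.kind}")
        if self.kind == "interlink" and self.beta is None:
            raise ValueError("interlink requires both constituents")


@dataclass(frozen=True)
class ResidueLinkage:
    """Protein-level K-X pair; residue numbers are 1-based protein coords."""

    protein_a: str
    res_a: int
    protein_b: str
    res_b: tuple[int, ...]  # ambiguity interval, length 1 when localized
    linker: str

    @property
    def res_b_label(self) -> str:
        if len(self.res_b) == 1:
            return str(self.res_b[0])
        return f"({self.res_b[0]}-{self.res_b[-1]})"


def _base_mass(psm: PSM) -> float:
    """Peptide mass with cross-link remnant masses stripped."""
    rem = sum(m.mass for m in psm.peptide.mods
              if m.name in ("alkene", "sulfenic", "thiol"))
    return psm.peptide.mass - rem


def _ppm(measured: float, expected: float) -> float:
    return (measured - expected) / expected * 1e6


def assemble(
    result: SearchResult,
    linker: CrosslinkerSpec,
    tol: Tolerances = Tolerances(),
) -> list[CrosslinkID]:
    """Classify each MS2 precursor from its identified MS3 children.

    An interlink needs an alkene-side PSM, a sulfenic/thiol-side PSM and
    a signature pair covering the corresponding MS2 peaks; dead-ends and
    intralinks are single-fragment species matched against their mass
    models.  Every emitted ID passes the precursor consistency check.
    """
    by_parent: dict[int, list[PSM]] = {}
    for psm in result.psms.values():
        if psm.parent_scan is None or psm.parent_scan not in result.ms2:
            raise ValueError(
                f"MS3 scan {psm.scan_id} lacks a resolvable MS2 parent")
        by_parent.setdefault(psm.parent_scan, []).append(psm)

    out: list[CrosslinkID] = []
    for ms2_scan, psms in by_parent.items():
        ms2 = result.ms2[ms2_scan]
        M = neutral_from_mz(ms2.precursor_mz, ms2.precursor_z)
        tol_ppm = tol.precursor_ppm
        pairs = result.pairs.get(ms2_scan, [])

        # intralink: one PSM carrying both alkene and thiol
        intra = [p for p in psms
                 if {m.name for m in p.peptide.mods
                     if m.name in ("alkene", "sulfenic", "thiol")}
                 == {"alkene", "thiol"}]
        made = False
        for p in intra:
            expected = _base_mass(p) + linker.bridge_mass
            ppm = _ppm(M, expected)
            if abs(ppm) <= tol_ppm:
                out.append(CrosslinkID(
                    kind="intralink", ms2_scan=ms2_scan, linker=linker.name,
                    alpha=p, beta=None, ppm_error=ppm, score=p.score,
                    is_decoy=p.is_decoy))
                made = True
        if made:
            continue

        alk = [p for p in psms if p.remnant_name == "alkene"
               and len(p.peptide.mods) >= 1 and p not in intra]
        st = [p for p in psms if p.remnant_name in ("sulfenic", "thiol")]

        # interlink: alpha (alkene) x beta (sulfenic/thiol), best ppm wins
        best: tuple[float, PSM, PSM] | None = None
        for a, b in itertools.product(alk, st):
            if a.scan_id == b.scan_id:
                continue
            expected = _base_mass(a) + _base_mass(b) + linker.bridge_mass
            ppm = _ppm(M, expected)
            if abs(ppm) <= tol_ppm:
                if best is None or abs(ppm) < abs(best[0]):
                    best = (ppm, a, b)
        if best is not None and pairs:
            ppm, a, b = best
            _orient_pairs(pairs, result, a, b)
            out.append(CrosslinkID(
                kind="interlink", ms2_scan=ms2_scan, linker=linker.name,
                alpha=a, beta=b, ppm_error=ppm,
                score=min(a.score, b.score),
                is_decoy=a.is_decoy or b.is_decoy))
            continue

        # dead-end: single constituent, precursor = peptide + bridge + H2O
        for p in alk + st:
            expected = _base_mass(p) + linker.deadend_mass
            ppm = _ppm(M, expected)
            if abs(ppm) <= tol_ppm:
                out.append(CrosslinkID(
                    kind="deadend", ms2_scan=ms2_scan, linker=linker.name,
                    alpha=p, beta=None, ppm_error=ppm, score=p.score,
                    is_decoy=p.is_decoy))
                break
    return out


def _orient_pairs(pairs: list[SignaturePair], result: SearchResult,
                  alpha: PSM, beta: PSM) -> None:
    """Fix pair orientation: the alkene side is the lysine peptide's peak."""
    ms2 = result.ms2.get(alpha.parent_scan)
    if ms2 is None:
        return
    a_idx = _peak_index(ms2, result.ms3[alpha.scan_id].precursor_mz)
    b_idx = _peak_index(ms2, result.ms3[beta.scan_id].precursor_mz)
    for pr in pairs:
        if {pr.idx_a, pr.idx_b} == {a_idx, b_idx}:
            if pr.idx_a != a_idx:
                pr.idx_a, pr.idx_b = pr.idx_b, pr.idx_a
                pr.z_a, pr.z_b = pr.z_b, pr.z_a
            pr.oriented = True


def _peak_index(ms2, mz_value: float, window: float = 0.01) -> int | None:
    best, best_d = None, window
    for i, (m, _) in enumerate(ms2.peaks):
        d = abs(m - mz_value)
        if d <= best_d:
            best, best_d = i, d
    return best


def fdr_filter(
    ids: Sequence[CrosslinkID], threshold: float = 0.01
) -> tuple[list[CrosslinkID], float]:
    """Target-decoy FDR filter at cross-link level.

    FDR = (#decoy-containing IDs) / (#target IDs) over the score-ranked
    prefix; the cut keeps the largest prefix with FDR <= threshold.
    Returns (target IDs retained, FDR estimate at the cut in percent).
    """
    if not ids:
        raise ValueError("no identifications to filter")
    if not any(not i.is_decoy for i in ids):
        raise ValueError("FDR undefined: no target identifications")
    ranked = sorted(ids, key=lambda i: -i.score)
    targets = decoys = 0
    cut = 0
    fdr_at_cut = 0.0
    for k, cid in enumerate(ranked, start=1):
        if cid.is_decoy:
            decoys += 1
        else:
            targets += 1
        if targets > 0 and decoys / targets <= threshold:
            cut = k
            fdr_at_cut = decoys / targets
    kept = [c for c in ranked[:cut] if not c.is_decoy]
    return kept, fdr_at_cut * 100.0


@dataclass
class CollapseResult:
    unique_sequences: set[tuple]
    linkages: list[ResidueLinkage]

    @property
    def n_sequences(self) -> int:
        return len(self.unique_sequences)

    @property
    def n_linkages(self) -> int:
        return len(self.linkages)


def _protein_site(psm: PSM, position: int) -> tuple[str, int]:
    ref = psm.peptide.protein_ref
    if ref is None:
        raise ValueError(
            f"peptide {psm.peptide.sequence} not mapped to a protein")
    return ref.accession, ref.start + position - 1


def collapse(ids: Sequence[CrosslinkID]) -> CollapseResult:
    """Collapse spectrum-level IDs to unique sequences and K-X linkages.

    Sequence-level keys ignore site localization.  Linkage-level keys map
    the diazirine-side ambiguity set to a protein-residue interval.
    Idempotent and order-independent.
    """
    seqs: set[tuple] = set()
    linkages: dict[tuple, ResidueLinkage] = {}
    for cid in ids:
        if cid.kind == "interlink":
            assert cid.beta is not None
            key = ("interlink", cid.linker,
                   tuple(sorted((cid.alpha.peptide.sequence,
                                 cid.beta.peptide.sequence))))
            seqs.add(key)
            rem_a = cid.alpha.peptide.remnant
            prot_a, res_a = _protein_site(cid.alpha, rem_a.position)
            amb = cid.beta.ambiguity or (cid.beta.peptide.remnant.position,)
            sites_b = tuple(sorted(
                _protein_site(cid.beta, p)[1] for p in amb))
            prot_b = cid.beta.peptide.protein_ref.accession
            lkey = (prot_a, res_a, prot_b, sites_b, cid.linker)
            linkages.setdefault(lkey, ResidueLinkage(
                protein_a=prot_a, res_a=res_a, protein_b=prot_b,
                res_b=sites_b, linker=cid.linker))
        else:
            seqs.add((cid.kind, cid.linker, cid.alpha.peptide.sequence))
    return CollapseResult(unique_sequences=seqs,
                          linkages=sorted(linkages.values(),
                                          key=lambda l: (l.protein_a, l.res_a,
                                                         l.protein_b, l.res_b)))


def replicate_overlap(replicates: Sequence[set]) -> dict[str, float]:
    """Reproducibility metrics across replicate linkage/sequence sets.

    Reports the fraction of the union found in >= 2 replicates, the
    fraction found in all, and the mean pairwise Jaccard index.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    union = set().union(*replicates)
    if not union:
        return {"frac_ge2": 0.0, "frac_all": 0.0, "mean_pairwise_jaccard": 0.0}
    counts = {x: sum(x in r for r in replicates) for x in union}
    ge2 = sum(1 for c in counts.values() if c >= 2) / len(union)
    al = sum(1 for c in counts.values() if c == len(replicates)) / len(union)
    jacc = []
    for a, b in itertools.combinations(replicates, 2):
        u = a | b
        jacc.append(len(a & b) / len(u) if u else 1.0)
    return {"frac_ge2": ge2, "frac_all": al,
            "mean_pairwise_jaccard": sum(jacc) / len(jacc)}


def ids_to_tsv(ids: Sequence[CrosslinkID], path: str | Path) -> None:
    rows = []
    for c in ids:
        rows.append({
            "kind": c.kind, "ms2_scan": c.ms2_scan, "linker": c.linker,
            "alpha_seq": c.alpha.peptide.sequence,
            "alpha_mods": ";".join(f"{m.name}@{m.position}"
                                   for m in c.alpha.peptide.mods),
            "beta_seq": c.beta.peptide.sequence if c.beta else "",
            "beta_mods": (";".join(f"{m.name}@{m.position}"
                                   for m in c.beta.peptide.mods)
                          if c.beta else ""),
            "beta_ambiguity": (";".join(map(str, c.beta.ambiguity))
                               if c.beta else ""),
            "ppm_error": round(c.ppm_error, 4),
            "score": round(c.score, 3),
            "is_decoy": c.is_decoy,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def linkages_to_tsv(linkages: Sequence[ResidueLinkage], path: str | Path) -> None:
    rows = [{
        "protein_a": l.protein_a, "res_a": l.res_a,
        "protein_b": l.protein_b, "res_b": l.res_b_label,
        "linker": l.linker,
    } for l in linkages]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def linkages_to_xinet_csv(
    linkages: Sequence[ResidueLinkage], path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """xiNET-compatible CSV (Protein1, Protein2, Res1, Res2, Score).

    Ambiguity intervals are exported at their first residue.
    """
    rows = []
    for i, l in enumerate(linkages):
        rows.append({
            "Protein1": l.protein_a, "Protein2": l.protein_b,
            "Res1": l.res_a, "Res2": l.res_b[0],
            "Score": scores[i] if scores is not None else 1.0,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
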