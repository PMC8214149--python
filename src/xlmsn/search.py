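"""MS2 signature-pair detection and MS3 peptide-spectrum matching.

The MS2 stage looks for fragment-pair signatures of cleavable linkers:
two peaks whose neutral masses reconstruct the precursor either as
alkene + sulfenic (A+S = M) or, after sulfenic dehydration, as
alkene + thiol (A+T = M - H2O).  For symmetric linkers (DSSO) the
alkene/thiol doublet of the same peptide (spacing 31.9721 Da) is used as
corroboration.  The MS3 stage scores remnant-modified peptide candidates
against b/y ladders with a binomial-tail score and reports site
localization ambiguity sets for the diazirine end.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy.stats import binom

from .chem import (
    CrosslinkerSpec,
    Mod,
    ModifiedPeptide,
    VARIABLE_MODS,
    WATER,
    fragment_ions,
    mz,
    neutral_from_mz,
)
from .msn_io import MSnSpectrum
from .seqdb import DigestIndex, _alkene_positions, candidate_peptides

__all__ = [
    "Tolerances",
    "SignaturePair",
    "PSM",
    "assign_charges",
    "find_signature_pairs",
    "score_psm",
    "localize_site",
    "search_ms3",
    "SearchResult",
    "search_spectra",
]

DSSO_DOUBLET = 31.9721  # thiol - alkene spacing, Da


@dataclass(frozen=True)
class Tolerances:
    precursor_ppm: float = 20.0
    pair_ppm: float = 20.0
    ms3_window_da: float = 0.6  # +/- Da for MS3 fragment matching

    def __post_init__(self) -> None:
        if min(self.precursor_ppm, self.pair_ppm, self.ms3_window_da) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SignaturePair:
    """An MS2 fragment pair reconstructing the precursor mass."""

    scan_id: int
    idx_a: int  # peak index of the putative alkene-side fragment
    idx_b: int  # peak index of the sulfenic/thiol-side fragment
    z_a: int
    z_b: int
    pair_type: str  # "A+S" or "A+T"
    linker: str
    ppm_error: float
    oriented: bool = False  # True once MS3 evidence fixed the alkene side
    doublet_corroborated: bool = False


@dataclass
class PSM:
    """An MS3 peptide-spectrum match."""

    scan_id: int
    parent_scan: int | None
    peptide: ModifiedPeptide
    score: float
    matched: int
    n_theoretical: int
    ambiguity: tuple[int, ...] = ()  # remnant positions tied in score
    is_decoy: bool = False

    @property
    def remnant_name(self) -> str | None:
        r = self.peptide.remnant
        return r.name if r is not None else None


def assign_charges(spectrum: MSnSpectrum, max_z: int | None = None
                   ) -> list[list[int]]:
    """Candidate charge hypotheses per peak: 1..(precursor_z - 1)."""
    top = spectrum.precursor_z - 1 if max_z is None else max_z
    top = max(1, top)
    hyp = list(range(1, top + 1))
    return [list(hyp) for _ in spectrum.peaks]


def find_signature_pairs(
    spectrum: MSnSpectrum,
    linker: CrosslinkerSpec,
    tol: Tolerances = Tolerances(),
) -> list[SignaturePair]:
    """All peak pairs satisfying A+S = M or A+T = M - H2O within tolerance.

    Fragment charges are constrained to sum to the precursor charge
    (protons are conserved when CID splits the bridge), which suppresses
    chance pairings.  One pair is emitted per unordered peak pair and
    pair type, keeping the best charge hypothesis by |ppm|.  Orientation
    (which peak is the alkene side) is provisional until MS3 evidence is
    integrated.  For symmetric linkers, same-peptide alkene/thiol
    doublets at 31.9721 Da spacing corroborate pairs sharing a peak with
    a doublet.
    """
    M = neutral_from_mz(spectrum.precursor_mz, spectrum.precursor_z)
    charges = assign_charges(spectrum)
    # flatten (neutral, peak index, z), sorted for windowed lookup
    entries: list[tuple[float, int, int]] = []
    for i, (pmz, _) in enumerate(spectrum.peaks):
        for z in charges[i]:
            entries.append((neutral_from_mz(pmz, z), i, z))
    entries.sort()
    neutrals = [e[0] for e in entries]

    best: dict[tuple[int, int, str], SignaturePair] = {}
    targets = (("A+S", M), ("A+T", M - WATER))
    tol_da = M * tol.pair_ppm * 1e-6
    for ni, i, zi in entries:
        for ptype, total in targets:
            want = total - ni
            lo = bisect_left(neutrals, want - tol_da)
            hi = bisect_right(neutrals, want + tol_da)
            for k in range(lo, hi):
                nj, j, zj = entries[k]
                if j <= i:  # unordered; also excludes self-pairing
                    continue
                if zi + zj != spectrum.precursor_z:  # charge conservation
                    continue
                ppm = (ni + nj - total) / M * 1e6
                key = (i, j, ptype)
                prev = best.get(key)
                if prev is None or abs(ppm) < abs(prev.ppm_error):
                    best[key] = SignaturePair(
                        scan_id=spectrum.scan_id, idx_a=i, idx_b=j,
                        z_a=zi, z_b=zj, pair_type=ptype,
                        linker=linker.name, ppm_error=ppm)
    pairs = sorted(best.values(), key=lambda p: (p.idx_a, p.idx_b, p.pair_type))

    if linker.symmetric and pairs:
        doublet_members = _doublet_peaks(spectrum, tol)
        for p in pairs:
            if p.idx_a in doublet_members or p.idx_b in doublet_members:
                p.doublet_corroborated = True
    return pairs


def _doublet_peaks(spectrum: MSnSpectrum, tol: Tolerances) -> set[int]:
    """Peak indices participating in a 31.9721 Da alkene/thiol doublet."""
    out: set[int] = set()
    charges = assign_charges(spectrum)
    peaks = spectrum.peaks
    for i, (mi, _) in enumerate(peaks):
        for j in range(i + 1, len(peaks)):
            mj = peaks[j][0]
            for z in charges[i]:
                delta = (mj - mi) * z
                if abs(delta - DSSO_DOUBLET) <= max(mi, mj) * z * tol.pair_ppm * 1e-6:
                    out.add(i)
                    out.add(j)
    return out


def score_psm(
    ms3: MSnSpectrum,
    candidate: ModifiedPeptide,
    tol: Tolerances = Tolerances(),
) -> PSM:
    """Binomial-tail score of a candidate against an MS3 spectrum.

    score = -log10 P(X >= k) with X ~ Binomial(n, p), where n is the
    theoretical b/y peak count (neutral-loss companions included for
    sulfenic candidates), k the number matched within the Da window, and
    p the per-peak chance match probability (window width x observed
    peak density).  Higher is better.
    """
    has_sulfenic = any(m.name == "sulfenic" for m in candidate.mods)
    theo = fragment_ions(candidate, ("b", "y"), neutral_loss=has_sulfenic)
    theo_mz = sorted(mz(m, 1) for _, m in theo)
    obs = [p[0] for p in ms3.peaks]
    n = len(theo_mz)
    k = 0
    for t in theo_mz:
        lo = bisect_left(obs, t - tol.ms3_window_da)
        if lo < len(obs) and obs[lo] <= t + tol.ms3_window_da:
            k += 1
    if obs:
        span = max(obs) - min(obs)
        density = len(obs) / span if span > 0 else 1.0
        p = min(0.999, max(1e-6, 2.0 * tol.ms3_window_da * density))
    else:
        p = 1e-6
    # survival function at k-1 gives P(X >= k); clamp to avoid log(0)
    tail = float(binom.sf(k - 1, n, p)) if k > 0 else 1.0
    score = -math.log10(max(tail, 1e-300))
    return PSM(
        scan_id=ms3.scan_id, parent_scan=ms3.parent_scan,
        peptide=candidate, score=score, matched=k, n_theoretical=n,
        is_decoy=candidate.is_decoy)


TIE_TOLERANCE = 0.01  # score delta within which localizations are tied


def localize_site(psms: Sequence[PSM], *, min_score: float = 5.0
                  ) -> PSM | None:
    """Pick the top PSM and collect its site-localization ambiguity set.

    The ambiguity set holds every remnant position of the same peptide
    sequence (same modification names) whose score ties the best within
    ``TIE_TOLERANCE``.  Returns None when nothing clears ``min_score``.
    """
    if not psms:
        raise ValueError("localize_site requires >= 1 PSM")
    best = max(psms, key=lambda p: p.score)
    if best.score < min_score:
        return None
    names = tuple(sorted(m.name for m in best.peptide.mods))
    positions: set[int] = set()
    for p in psms:
        if (p.peptide.sequence == best.peptide.sequence
                and tuple(sorted(m.name for m in p.peptide.mods)) == names
                and best.score - p.score < TIE_TOLERANCE
                and p.peptide.remnant is not None):
            positions.add(p.peptide.remnant.position)
    return replace(best, ambiguity=tuple(sorted(positions)))


# ---------------------------------------------------------------------------
# Candidate enumeration and the spectrum-level search driver


def _variable_mod_sets(
    sequence: str, var_names: Sequence[str], max_var: int,
    at_protein_nterm: bool,
) -> Iterable[tuple[Mod, ...]]:
    """Enumerate placements of up to ``max_var`` variable modifications."""
    slots: list[Mod] = []
    for name in var_names:
        target, delta = VARIABLE_MODS[name]
        if target == "nterm":
            if at_protein_nterm:
                slots.append(Mod(1, name, delta))
        elif target == "Q":  # pyroGlu applies to an N-terminal Q only
            if sequence[0] == "Q":
                slots.append(Mod(1, name, delta))
        else:
            for i, r in enumerate(sequence, start=1):
                if r == target:
                    slots.append(Mod(i, name, delta))
    yield ()
    for k in range(1, min(max_var, len(slots)) + 1):
        for combo in itertools.combinations(slots, k):
            if len({m.position for m in combo}) == len(combo):
                yield combo


def _intralink_candidates(
    index: DigestIndex, linker: CrosslinkerSpec, mass: float, ppm: float
) -> list[ModifiedPeptide]:
    """Peptides carrying alkene (K) + thiol (X) matching the mass window."""
    from .chem import ProteinRef

    delta = linker.alkene.mono_mass + linker.thiol.mono_mass
    out: list[ModifiedPeptide] = []
    for span in index.in_window(mass - delta, ppm):
        k_positions = _alkene_positions(
            span, index.protein_length(span.accession),
            remnant_blocked=index.params.remnant_blocked_cleavage)
        for kp in k_positions:
            for xp, r in enumerate(span.sequence, start=1):
                if xp == kp or r not in linker.end_b_targets:
                    continue
                out.append(ModifiedPeptide(
                    sequence=span.sequence,
                    mods=(Mod(kp, "alkene", linker.alkene.mono_mass),
                          Mod(xp, "thiol", linker.thiol.mono_mass)),
                    protein_ref=ProteinRef(span.accession, span.start),
                    is_decoy=span.is_decoy))
    return out


def search_ms3(
    ms3: MSnSpectrum,
    index: DigestIndex,
    linker: CrosslinkerSpec,
    tol: Tolerances = Tolerances(),
    *,
    min_score: float = 5.0,
    var_mods: Sequence[str] = (),
    max_var: int = 4,
) -> PSM | None:
    """Identify one MS3 spectrum: enumerate remnant hypotheses, score, localize."""
    M = neutral_from_mz(ms3.precursor_mz, ms3.precursor_z)
    candidates: list[ModifiedPeptide] = []
    if not var_mods:
        candidates += candidate_peptides(index, linker, "A", M, tol.precursor_ppm)
        candidates += candidate_peptides(index, linker, "B", M, tol.precursor_ppm)
        candidates += _intralink_candidates(index, linker, M, tol.precursor_ppm)
    else:
        # distinct variable-mod mass offsets shift the query window
        deltas = sorted({
            round(sum(m.mass for m in combo), 6): combo
            for combo in _modset_mass_reps(var_mods, max_var)
        }.items())
        for dmass, _ in deltas:
            base = M - dmass
            raw = (candidate_peptides(index, linker, "A", base, tol.precursor_ppm)
                   + candidate_peptides(index, linker, "B", base, tol.precursor_ppm)
                   + _intralink_candidates(index, linker, base, tol.precursor_ppm))
            for cand in raw:
                at_nterm = (cand.protein_ref is not None
                            and cand.protein_ref.start == 1)
                for combo in _variable_mod_sets(
                        cand.sequence, var_mods, max_var, at_nterm):
                    if abs(sum(m.mass for m in combo) - dmass) > 1e-6:
                        continue
                    taken = {m.position for m in cand.mods}
                    if any(m.position in taken for m in combo):
                        continue
                    candidates.append(replace(cand, mods=cand.mods + combo))
    if not candidates:
        return None
    psms = [score_psm(ms3, c, tol) for c in candidates]
    return localize_site(psms, min_score=min_score)


def _modset_mass_reps(var_names: Sequence[str], max_var: int):
    """One representative placement-free combo per variable-mod multiset."""
    deltas = [(name, VARIABLE_MODS[name][1]) for name in var_names]
    for k in range(0, max_var + 1):
        for combo in itertools.combinations_with_replacement(deltas, k):
            yield tuple(Mod(0, n, d) for n, d in combo)


@dataclass
class SearchResult:
    pairs: dict[int, list[SignaturePair]]  # MS2 scan id -> pairs
    psms: dict[int, PSM]  # MS3 scan id -> best PSM
    ms2: dict[int, MSnSpectrum]
    ms3: dict[int, MSnSpectrum]


def search_spectra(
    spectra: Sequence[MSnSpectrum],
    index: DigestIndex,
    linker: CrosslinkerSpec,
    tol: Tolerances = Tolerances(),
    *,
    min_score: float = 5.0,
    var_mods: Sequence[str] = (),
) -> SearchResult:
    """Run pair detection on every MS2 and PSM search on every MS3."""
    ms2 = {s.scan_id: s for s in spectra if s.ms_level == 2}
    ms3 = {s.scan_id: s for s in spectra if s.ms_level == 3}
    pairs = {sid: find_signature_pairs(s, linker, tol) for sid, s in ms2.items()}
    psms: dict[int, PSM] = {}
    for sid, s in ms3.items():
        if s.parent_scan not in ms2:
            raise ValueError(f"MS3 scan {sid} references missing MS2 parent "
                             f"{s.parent_scan}")
        hit = search_ms3(s, index, linker, tol,
                         min_score=min_score, var_mods=var_mods)
        if hit is not None:
            psms[sid] = hit
    return SearchResult(pairs=pairs, psms=psms, ms2=ms2, ms3=ms3)
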