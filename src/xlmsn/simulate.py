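"""Ground-truth simulator for cleavable cross-link MS^n experiments.

Generates cross-linked species (interlinks, the two dead-end types,
intralinks) from a target protein database, renders their MS2/MS3 spectra
with the fragmentation rules of sulfoxide-containing linkers, and builds
toy multi-model Calpha structures with planted distances.  This is the
stand-in for a real photo-cross-linking acquisition: every identification
made downstream can be checked against the truth manifest.

What is emulated: the MS2 signature fragment pair (alkene side vs
sulfenic/thiol side, with sulfenic->thiol dehydration), top-4
data-dependent MS3 selection, b/y ladders with sulfenic neutral loss,
precursor charges >= 3, Gaussian ppm mass error, uniform noise peaks, and
a configurable residue-preference distribution for the diazirine end.
Not emulated: isotope envelopes, chromatography, intensity physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    CrosslinkerSpec,
    Mod,
    ModifiedPeptide,
    ProteinRef,
    WATER,
    crosslinked_pair_mass,
    fragment_ions,
    get_linker,
    mz,
)
from .msn_io import MSnSpectrum
from .seqdb import (
    DigestParams,
    PeptideSpan,
    ProteinRecord,
    _alkene_positions,
    digest,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "DEFAULT_PREFERENCE",
    "simulate_crosslinks",
    "render_spectra",
    "truth_to_tsv",
    "PlantedLinkage",
    "make_toy_structures",
]

# Diazirine labeling profile used by default: glutamic acid dominates
# (30% of targeted residues), with A/D/L/Y relatively favored; the
# remaining 15 residues share the residual weight uniformly so the
# distribution sums to exactly 1.
DEFAULT_PREFERENCE: dict[str, float] = {
    "E": 0.30, "L": 0.073, "A": 0.072, "D": 0.068, "Y": 0.064,
    **{r: (1.0 - 0.577) / 15 for r in "GSPVTCINQKMHFRW"},
}


@dataclass
class SimConfig:
    linker: str = "SDASO-M"
    n_interlinks: int = 100
    n_deadend_nhs: int = 20
    n_deadend_diazirine: int = 20
    n_intralinks: int = 20
    residue_preference: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREFERENCE))
    charges: tuple[int, ...] = (3, 4, 5)
    ppm_sigma: float = 5.0
    noise_peaks: int = 20
    seed: int = 0
    digest: DigestParams = field(default_factory=DigestParams)
    # thiol dominates its hydrated sulfenic precursor ~4:1 in MS2
    sulfenic_thiol_ratio: float = 0.25

    def __post_init__(self) -> None:
        w = self.residue_preference
        if any(v < 0 for v in w.values()) or not any(v > 0 for v in w.values()):
            raise ValueError("preference weights must be >= 0, not all zero")
        if any(z < 3 for z in self.charges):
            raise ValueError("precursor charges must be >= 3")
        for n in (self.n_interlinks, self.n_deadend_nhs,
                  self.n_deadend_diazirine, self.n_intralinks):
            if n < 0:
                raise ValueError("species counts must be >= 0")


@dataclass
class TruthRecord:
    kind: str  # interlink | deadend_nhs_hydrolyzed | deadend_diazirine_hydrolyzed | intralink
    linker: str
    alpha: ModifiedPeptide  # base peptide, no remnant (K/NHS side when present)
    alpha_site: int | None  # 1-based peptide position of the lysine
    beta: ModifiedPeptide | None  # diazirine-side peptide (None for dead-ends)
    beta_site: int | None
    # filled in by render_spectra:
    precursor_mz: float | None = None
    precursor_z: int | None = None
    ms2_scan: int | None = None
    ms3_scans: tuple[int, ...] = ()

    @property
    def alpha_protein_site(self) -> int | None:
        if self.alpha_site is None:
            return None
        return self.alpha.site_in_protein(self.alpha_site)

    @property
    def beta_protein_site(self) -> int | None:
        if self.beta_site is None:
            return None
        host = self.beta if self.beta is not None else self.alpha
        return host.site_in_protein(self.beta_site)

    def neutral_mass(self, linker: CrosslinkerSpec) -> float:
        if self.kind == "interlink":
            assert self.beta is not None
            return crosslinked_pair_mass(self.alpha, self.beta, linker)
        if self.kind in ("deadend_nhs_hydrolyzed", "deadend_diazirine_hydrolyzed"):
            return self.alpha.mass + linker.bridge_mass + WATER
        if self.kind == "intralink":
            return self.alpha.mass + linker.bridge_mass
        raise ValueError(f"unknown species kind {self.kind}")


def _span_peptide(span: PeptideSpan) -> ModifiedPeptide:
    return ModifiedPeptide(
        sequence=span.sequence,
        protein_ref=ProteinRef(span.accession, span.start),
        is_decoy=span.is_decoy,
    )


class _SitePools:
    """Sampling pools for NHS (lysine) and diazirine (any-residue) sites."""

    def __init__(self, db: Sequence[ProteinRecord], cfg: SimConfig):
        plen = {r.accession: len(r.sequence) for r in db}
        spans: list[PeptideSpan] = []
        seen: set[tuple[str, int, int]] = set()
        for rec in db:
            for sp in digest(rec, cfg.digest):
                key = (sp.accession, sp.start, sp.end)
                if key not in seen:
                    seen.add(key)
                    spans.append(sp)
        self.k_sites: list[tuple[PeptideSpan, int]] = []
        self.x_by_residue: dict[str, list[tuple[PeptideSpan, int]]] = {}
        for sp in spans:
            for pos in _alkene_positions(
                    sp, plen[sp.accession],
                    remnant_blocked=cfg.digest.remnant_blocked_cleavage):
                self.k_sites.append((sp, pos))
            for pos, r in enumerate(sp.sequence, start=1):
                self.x_by_residue.setdefault(r, []).append((sp, pos))
        if not self.k_sites:
            raise ValueError("database has no lysine-containing peptides")

    def draw_k(self, rng: np.random.Generator) -> tuple[PeptideSpan, int]:
        return self.k_sites[rng.integers(len(self.k_sites))]

    def draw_x(self, rng: np.random.Generator,
               preference: dict[str, float]) -> tuple[PeptideSpan, int]:
        """Two-stage draw: residue type by preference weight, then a
        uniform position of that type.  The realized residue-type
        fractions therefore converge to the (renormalized) weights
        regardless of database composition."""
        avail = [r for r, w in preference.items()
                 if w > 0 and r in self.x_by_residue]
        if not avail:
            raise ValueError("no diazirine-targetable residues in database")
        w = np.array([preference[r] for r in avail])
        r = avail[rng.choice(len(avail), p=w / w.sum())]
        pool = self.x_by_residue[r]
        return pool[rng.integers(len(pool))]


def simulate_crosslinks(
    db: Sequence[ProteinRecord], cfg: SimConfig
) -> list[TruthRecord]:
    """Draw ground-truth cross-linked species from a target database."""
    rng = np.random.default_rng(cfg.seed)
    linker = get_linker(cfg.linker)
    pools = _SitePools(db, cfg)
    out: list[TruthRecord] = []

    for _ in range(cfg.n_interlinks):
        a_span, a_pos = pools.draw_k(rng)
        b_span, b_pos = pools.draw_x(rng, cfg.residue_preference)
        out.append(TruthRecord(
            kind="interlink", linker=linker.name,
            alpha=_span_peptide(a_span), alpha_site=a_pos,
            beta=_span_peptide(b_span), beta_site=b_pos,
        ))
    # NHS end hydrolyzed -> the peptide is attached via the diazirine end
    for _ in range(cfg.n_deadend_nhs):
        b_span, b_pos = pools.draw_x(rng, cfg.residue_preference)
        out.append(TruthRecord(
            kind="deadend_nhs_hydrolyzed", linker=linker.name,
            alpha=_span_peptide(b_span), alpha_site=None,
            beta=None, beta_site=b_pos,
        ))
    # diazirine end hydrolyzed -> attached via NHS ester on a lysine
    for _ in range(cfg.n_deadend_diazirine):
        a_span, a_pos = pools.draw_k(rng)
        out.append(TruthRecord(
            kind="deadend_diazirine_hydrolyzed", linker=linker.name,
            alpha=_span_peptide(a_span), alpha_site=a_pos,
            beta=None, beta_site=None,
        ))
    # intralink: both ends on one peptide
    intra_pool = [(sp, pos) for sp, pos in pools.k_sites if len(sp.sequence) >= 2]
    for _ in range(cfg.n_intralinks):
        sp, k_pos = intra_pool[rng.integers(len(intra_pool))]
        others = [i for i in range(1, len(sp.sequence) + 1) if i != k_pos]
        w = np.array([cfg.residue_preference.get(sp.sequence[i - 1], 0.0)
                      for i in others])
        if w.sum() == 0:
            w = np.ones(len(others))
        x_pos = others[rng.choice(len(others), p=w / w.sum())]
        out.append(TruthRecord(
            kind="intralink", linker=linker.name,
            alpha=_span_peptide(sp), alpha_site=k_pos,
            beta=None, beta_site=x_pos,
        ))
    return out


def _with_mods(p: ModifiedPeptide, *mods: Mod) -> ModifiedPeptide:
    return replace(p, mods=tuple(mods))


def _noisy(value: float, rng: np.random.Generator, ppm_sigma: float) -> float:
    if ppm_sigma <= 0:
        return value
    return value * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)


def _ms2_fragments(
    rec: TruthRecord, linker: CrosslinkerSpec, cfg: SimConfig, z: int
) -> list[tuple[ModifiedPeptide, int, float]]:
    """(remnant-modified peptide, fragment charge, intensity) for one MS2."""
    alk, sul, thi = linker.alkene, linker.sulfenic, linker.thiol
    ratio = cfg.sulfenic_thiol_ratio
    frags: list[tuple[ModifiedPeptide, int, float]] = []
    if rec.kind == "interlink":
        assert rec.beta is not None and rec.alpha_site and rec.beta_site
        za = max(1, z // 2)
        zb = max(1, z - za)
        a_alk = _with_mods(rec.alpha, Mod(rec.alpha_site, "alkene", alk.mono_mass))
        b_thi = _with_mods(rec.beta, Mod(rec.beta_site, "thiol", thi.mono_mass))
        b_sul = _with_mods(rec.beta, Mod(rec.beta_site, "sulfenic", sul.mono_mass))
        frags += [(a_alk, za, 100.0), (b_thi, zb, 80.0), (b_sul, zb, 80.0 * ratio)]
        if linker.symmetric:
            # symmetric linkers cleave either C-S bond: both assignments
            a_sul = _with_mods(rec.alpha, Mod(rec.alpha_site, "sulfenic", sul.mono_mass))
            a_thi = _with_mods(rec.alpha, Mod(rec.alpha_site, "thiol", thi.mono_mass))
            b_alk = _with_mods(rec.beta, Mod(rec.beta_site, "alkene", alk.mono_mass))
            frags += [(b_alk, zb, 95.0), (a_thi, za, 76.0),
                      (a_sul, za, 76.0 * ratio)]
    elif rec.kind == "deadend_nhs_hydrolyzed":
        site = rec.beta_site
        assert site is not None
        fz = max(1, min(2, z - 1))
        frags += [
            (_with_mods(rec.alpha, Mod(site, "thiol", thi.mono_mass)), fz, 100.0),
            (_with_mods(rec.alpha, Mod(site, "sulfenic", sul.mono_mass)), fz,
             100.0 * ratio),
        ]
    elif rec.kind == "deadend_diazirine_hydrolyzed":
        assert rec.alpha_site is not None
        fz = max(1, min(2, z - 1))
        frags.append(
            (_with_mods(rec.alpha, Mod(rec.alpha_site, "alkene", alk.mono_mass)),
             fz, 100.0))
    elif rec.kind == "intralink":
        assert rec.alpha_site is not None and rec.beta_site is not None
        fz = max(1, min(2, z - 1))
        frags.append((
            _with_mods(rec.alpha,
                       Mod(rec.alpha_site, "alkene", alk.mono_mass),
                       Mod(rec.beta_site, "thiol", thi.mono_mass)),
            fz, 100.0))
    else:
        raise ValueError(f"unknown species kind {rec.kind}")
    return frags


def render_spectra(
    truth: Sequence[TruthRecord], cfg: SimConfig
) -> list[MSnSpectrum]:
    """Render MS2 + data-dependent top-4 MS3 spectra for each species.

    Mutates the truth records in place with precursor and scan lineage.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    linker = get_linker(cfg.linker)
    spectra: list[MSnSpectrum] = []
    scan = 0
    charges = np.array(sorted(cfg.charges))
    for rec in truth:
        z = int(charges[rng.integers(len(charges))])
        neutral = rec.neutral_mass(linker)
        prec_mz = mz(neutral, z)
        frags = _ms2_fragments(rec, linker, cfg, z)

        scan += 1
        ms2_scan = scan
        peaks = [(_noisy(mz(p.mass, fz), rng, cfg.ppm_sigma), inten)
                 for p, fz, inten in frags]
        max_mz = max(m for m, _ in peaks)
        for _ in range(cfg.noise_peaks):
            peaks.append((float(rng.uniform(150.0, max_mz * 1.05)),
                          float(rng.uniform(1.0, 10.0))))
        ms2 = MSnSpectrum(
            scan_id=ms2_scan, ms_level=2,
            precursor_mz=_noisy(prec_mz, rng, cfg.ppm_sigma),
            precursor_z=z, peaks=peaks, parent_scan=None)
        spectra.append(ms2)

        # top-4 data-dependent MS3 on the most intense MS2 signal peaks
        order = sorted(range(len(frags)), key=lambda i: -frags[i][2])[:4]
        ms3_scans = []
        for i in order:
            pep, fz, _ = frags[i]
            frag_mz = peaks[i][0]  # noisy observed m/z becomes MS3 precursor
            scan += 1
            has_sulfenic = any(m.name == "sulfenic" for m in pep.mods)
            ions = fragment_ions(pep, ("b", "y"), neutral_loss=has_sulfenic)
            ms3_peaks = [
                (_noisy(mz(m, 1), rng, cfg.ppm_sigma),
                 float(rng.uniform(30.0, 100.0)))
                for _, m in ions
            ]
            mmax = max(m for m, _ in ms3_peaks)
            for _ in range(cfg.noise_peaks):
                ms3_peaks.append((float(rng.uniform(100.0, mmax * 1.05)),
                                  float(rng.uniform(1.0, 10.0))))
            spectra.append(MSnSpectrum(
                scan_id=scan, ms_level=3, precursor_mz=frag_mz,
                precursor_z=fz, peaks=ms3_peaks, parent_scan=ms2_scan))
            ms3_scans.append(scan)

        rec.precursor_mz = ms2.precursor_mz
        rec.precursor_z = z
        rec.ms2_scan = ms2_scan
        rec.ms3_scans = tuple(ms3_scans)
    return spectra


def truth_to_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        rows.append({
            "kind": t.kind,
            "linker": t.linker,
            "alpha_protein": t.alpha.protein_ref.accession if t.alpha.protein_ref else "",
            "alpha_seq": t.alpha.sequence,
            "alpha_site": t.alpha_protein_site or "",
            "beta_protein": (t.beta.protein_ref.accession
                             if t.beta is not None and t.beta.protein_ref else ""),
            "beta_seq": t.beta.sequence if t.beta is not None else "",
            "beta_site": t.beta_protein_site or "",
            "beta_residue": _beta_residue(t) or "",
            "precursor_mz": t.precursor_mz or "",
            "precursor_z": t.precursor_z or "",
            "ms2_scan": t.ms2_scan or "",
            "ms3_scans": ";".join(map(str, t.ms3_scans)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _beta_residue(t: TruthRecord) -> str | None:
    if t.beta_site is None:
        return None
    host = t.beta if t.beta is not None else t.alpha
    return host.sequence[t.beta_site - 1]


# ---------------------------------------------------------------------------
# Toy multi-model structures with planted Calpha-Calpha distances

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class PlantedLinkage:
    """A residue pair whose Calpha distance is planted per model."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    distances: tuple[float, ...]  # one per model, Angstrom


def make_toy_structures(
    n_models: int,
    plants: Sequence[PlantedLinkage],
    seed: int = 0,
    chains: dict[str, str] | None = None,
):
    """Build a synthetic Calpha-only multi-model structure.

    Returns ``(gemmi.Structure, pandas.DataFrame)`` where the table lists
    every planted distance per model.  Planted pairs are realized exactly;
    unplanted residues sit on jittered per-chain baselines.  ``chains``
    optionally gives each chain's residue sequence (one-letter); by
    default chains are poly-alanine with lysine at each planted ``res_a``.
    """
    import gemmi

    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    used: set[tuple[str, int]] = set()
    for pl in plants:
        if len(pl.distances) != n_models:
            raise ValueError("each plant needs one distance per model")
        if any(d < 0 for d in pl.distances):
            raise ValueError("infeasible distance plan: negative distance")
        for key in ((pl.chain_a, pl.res_a), (pl.chain_b, pl.res_b)):
            if key in used:
                raise ValueError(
                    f"infeasible distance plan: residue {key} planted twice")
            used.add(key)

    if chains is None:
        chain_ids = sorted({pl.chain_a for pl in plants}
                           | {pl.chain_b for pl in plants}) or ["A"]
        length: dict[str, int] = {c: 3 for c in chain_ids}
        for pl in plants:
            length[pl.chain_a] = max(length[pl.chain_a], pl.res_a + 1)
            length[pl.chain_b] = max(length[pl.chain_b], pl.res_b + 1)
        chains = {c: "A" * length[c] for c in chain_ids}
        for pl in plants:
            s = chains[pl.chain_a]
            chains[pl.chain_a] = s[:pl.res_a - 1] + "K" + s[pl.res_a:]
    for pl in plants:
        for c, r in ((pl.chain_a, pl.res_a), (pl.chain_b, pl.res_b)):
            if c not in chains or not (1 <= r <= len(chains[c])):
                raise ValueError(f"planted residue {c}:{r} outside chains")

    rng = np.random.default_rng(seed)
    chain_ids = sorted(chains)
    # per-chain jittered baselines, shared across models
    base: dict[tuple[str, int], np.ndarray] = {}
    for ci, c in enumerate(chain_ids):
        for i in range(1, len(chains[c]) + 1):
            base[(c, i)] = np.array([
                3.8 * i + rng.uniform(-0.5, 0.5),
                40.0 * ci + rng.uniform(-0.5, 0.5),
                rng.uniform(-0.5, 0.5),
            ])

    st = gemmi.Structure()
    rows = []
    for mi in range(n_models):
        coords = dict(base)
        for k, pl in enumerate(plants):
            anchor = np.array([2000.0 + 100.0 * k, -500.0, 0.0])
            coords[(pl.chain_a, pl.res_a)] = anchor
            coords[(pl.chain_b, pl.res_b)] = anchor + np.array(
                [pl.distances[mi], 0.0, 0.0])
            rows.append({
                "model": mi + 1,
                "chain_a": pl.chain_a, "res_a": pl.res_a,
                "chain_b": pl.chain_b, "res_b": pl.res_b,
                "distance": pl.distances[mi],
            })
        model = gemmi.Model(str(mi + 1))
        for c in chain_ids:
            chain = gemmi.Chain(c)
            for i, letter in enumerate(chains[c], start=1):
                res = gemmi.Residue()
                res.name = AA1TO3.get(letter, "ALA")
                res.seqid = gemmi.SeqId(i, " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                x, y, zc = coords[(c, i)]
                atom.pos = gemmi.Position(float(x), float(y), float(zc))
                atom.element = gemmi.Element("C")
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st, pd.DataFrame(rows)
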