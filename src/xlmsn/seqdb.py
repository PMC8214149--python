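"""FASTA I/O, in-silico digestion, decoy construction, candidate enumeration.

Digestion produces 1-based inclusive spans so peptides stay mapped to
protein coordinates -- required later when residue linkages are projected
onto structures.  Decoys are per-protein residue shuffles concatenated to
the target list, the classic target-decoy search-space construction.
"""

from __future__ import annotations

import random
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import (
    ALL_RESIDUES,
    WATER,
    CrosslinkerSpec,
    Mod,
    ModifiedPeptide,
    ProteinRef,
    RESIDUE_MASSES,
)

DECOY_PREFIX = "DECOY_"

__all__ = [
    "ProteinRecord",
    "DigestParams",
    "PeptideSpan",
    "read_fasta",
    "write_fasta",
    "digest",
    "make_decoys",
    "DigestIndex",
    "candidate_peptides",
    "DECOY_PREFIX",
]


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALL_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}")
        if self.is_decoy and not self.accession.startswith(DECOY_PREFIX):
            raise ValueError("decoy accession must carry the DECOY_ prefix")


# enzyme -> (cleavage residues, residue blocking cleavage when next)
ENZYMES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "trypsin": (frozenset("KR"), frozenset("P")),
    "chymotrypsin": (frozenset("FWYL"), frozenset("P")),
}

DEFAULT_MISSED = {"trypsin": 3, "chymotrypsin": 4}


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed: int | None = None  # None -> enzyme default (3 / 4)
    min_len: int = 4
    max_len: int = 50
    remnant_blocked_cleavage: bool = True

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.max_missed is not None and self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid length range")

    @property
    def missed(self) -> int:
        if self.max_missed is not None:
            return self.max_missed
        return DEFAULT_MISSED[self.enzyme]


@dataclass(frozen=True)
class PeptideSpan:
    """A digest peptide: 1-based inclusive coordinates within its protein."""

    accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    is_decoy: bool = False

    @property
    def base_mass(self) -> float:
        return sum(RESIDUE_MASSES[r] for r in self.sequence) + WATER


def read_fasta(path: str | Path, *, strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, order preserved.

    Sequences are uppercased.  Duplicate accessions are an error.  In
    lenient mode records with non-standard residues are dropped instead
    of raising.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        seq = str(rec.seq).upper()
        try:
            records.append(
                ProteinRecord(acc, seq, is_decoy=acc.startswith(DECOY_PREFIX)))
        except ValueError:
            if strict:
                raise
    if not records:
        raise ValueError(f"no FASTA records read from {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.accession, description="")
         for r in records),
        str(path),
        "fasta",
    )


def cleavage_sites(sequence: str, enzyme: str) -> list[int]:
    """0-based indices i such that the bond after residue i is cleaved."""
    residues, blockers = ENZYMES[enzyme]
    n = len(sequence)
    return [
        i for i in range(n - 1)
        if sequence[i] in residues and sequence[i + 1] not in blockers
    ]


def digest(protein: ProteinRecord, params: DigestParams) -> list[PeptideSpan]:
    """Fully-specific digest with up to ``params.missed`` missed cleavages."""
    seq = protein.sequence
    sites = cleavage_sites(seq, params.enzyme)
    # fragment boundaries: start indices of each fully-cleaved fragment
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(seq)]  # exclusive
    out: list[PeptideSpan] = []
    nfrag = len(starts)
    for i in range(nfrag):
        for j in range(i, min(i + params.missed + 1, nfrag)):
            a, b = starts[i], ends[j]
            if params.min_len <= b - a <= params.max_len:
                out.append(PeptideSpan(
                    accession=protein.accession,
                    start=a + 1,
                    end=b,
                    sequence=seq[a:b],
                    missed_cleavages=j - i,
                    is_decoy=protein.is_decoy,
                ))
    return out


# Approximate vertebrate amino-acid frequencies for synthetic databases.
_AA_FREQS = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.018,
    "Q": 0.040, "E": 0.062, "G": 0.074, "H": 0.026, "I": 0.053,
    "L": 0.091, "K": 0.058, "M": 0.022, "F": 0.040, "P": 0.051,
    "S": 0.073, "T": 0.059, "W": 0.013, "Y": 0.033, "V": 0.063,
}


def random_proteins(
    n: int, length: int, seed: int, prefix: str = "SYN"
) -> list[ProteinRecord]:
    """Synthetic target proteins with realistic residue composition."""
    import numpy as np

    rng = np.random.default_rng(seed)
    letters = list(_AA_FREQS)
    p = np.array(list(_AA_FREQS.values()))
    p = p / p.sum()
    out = []
    for i in range(n):
        seq = "".join(rng.choice(letters, size=length, p=p))
        out.append(ProteinRecord(f"{prefix}{i + 1:04d}", seq))
    return out


def make_decoys(
    db: Sequence[ProteinRecord], seed: int, *, method: str = "shuffle"
) -> list[ProteinRecord]:
    """Concatenate one decoy per target onto the database.

    ``shuffle`` permutes each sequence with the given seed (composition
    preserved); ``reverse`` reverses it.  Input must be targets only.
    """
    if any(r.is_decoy for r in db):
        raise ValueError("input database must contain targets only")
    rng = random.Random(seed)
    decoys: list[ProteinRecord] = []
    for rec in db:
        if method == "shuffle":
            letters = list(rec.sequence)
            rng.shuffle(letters)
            dseq = "".join(letters)
        elif method == "reverse":
            dseq = rec.sequence[::-1]
        else:
            raise ValueError(f"unknown decoy method {method!r}")
        decoys.append(
            ProteinRecord(DECOY_PREFIX + rec.accession, dseq, is_decoy=True))
    return list(db) + decoys


class DigestIndex:
    """Mass-sorted index of digest peptides for windowed candidate lookup."""

    def __init__(self, db: Sequence[ProteinRecord], params: DigestParams):
        self.params = params
        spans: list[PeptideSpan] = []
        self._protein_len = {r.accession: len(r.sequence) for r in db}
        seen: set[tuple[str, int, int]] = set()
        for rec in db:
            for sp in digest(rec, params):
                key = (sp.accession, sp.start, sp.end)
                if key not in seen:  # overlapping missed-cleavage dedup
                    seen.add(key)
                    spans.append(sp)
        spans.sort(key=lambda s: s.base_mass)
        self.spans = spans
        self._masses = [s.base_mass for s in spans]

    def __len__(self) -> int:
        return len(self.spans)

    def in_window(self, mass: float, ppm: float) -> list[PeptideSpan]:
        tol = mass * ppm * 1e-6
        lo = bisect_left(self._masses, mass - tol)
        hi = bisect_right(self._masses, mass + tol)
        return self.spans[lo:hi]

    def protein_length(self, accession: str) -> int:
        return self._protein_len[accession]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\tstart\tend\tsequence\tmissed_cleavages\n")
            for s in self.spans:
                fh.write(f"{s.accession}\t{s.start}\t{s.end}\t"
                         f"{s.sequence}\t{s.missed_cleavages}\n")


def _alkene_positions(
    span: PeptideSpan, protein_len: int, *, remnant_blocked: bool
) -> list[int]:
    """1-based peptide positions where an alkene-bearing K may sit.

    A remnant-blocked K cannot be a tryptic cleavage C-terminus, so the
    modified K must be internal -- unless the peptide ends at the protein
    C-terminus, where no cleavage happened.
    """
    n = len(span.sequence)
    out = []
    for i, r in enumerate(span.sequence, start=1):
        if r != "K":
            continue
        if remnant_blocked and i == n and span.end != protein_len:
            continue
        out.append(i)
    return out


def candidate_peptides(
    index: DigestIndex,
    linker: CrosslinkerSpec,
    side: str,
    mass: float,
    ppm: float = 20.0,
    *,
    moiety: str | None = None,
) -> list[ModifiedPeptide]:
    """Enumerate remnant-modified candidates matching a neutral-mass window.

    ``side="A"`` places the alkene on an eligible (uncleaved) lysine;
    ``side="B"`` places a sulfenic or thiol moiety on every residue the
    linker's second end can target.  For side B, ``moiety`` selects
    "sulfenic" or "thiol" (default: both enumerated).
    """
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    if len(index) == 0:
        raise ValueError("empty digest index")
    out: list[ModifiedPeptide] = []
    if side == "A":
        moieties = [linker.alkene]
    else:
        if moiety is None:
            moieties = [linker.sulfenic, linker.thiol]
        else:
            moieties = [linker.moiety(moiety)]
    for mo in moieties:
        base = mass - mo.mono_mass
        if base <= 0:
            continue
        for span in index.in_window(base, ppm):
            ref = ProteinRef(span.accession, span.start)
            if side == "A":
                positions = _alkene_positions(
                    span, index.protein_length(span.accession),
                    remnant_blocked=index.params.remnant_blocked_cleavage)
            else:
                targets = linker.end_b_targets
                positions = [
                    i for i, r in enumerate(span.sequence, start=1)
                    if r in targets
                ]
            for pos in positions:
                out.append(ModifiedPeptide(
                    sequence=span.sequence,
                    mods=(Mod(pos, mo.name, mo.mono_mass),),
                    protein_ref=ref,
                    is_decoy=span.is_decoy,
                ))
    return out
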