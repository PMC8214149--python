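"""Mass arithmetic for sulfoxide-containing MS-cleavable cross-linkers.

Covers elemental-formula parsing, monoisotopic masses, the remnant-moiety
registry for DSSO and the three SDASO linkers, modified-peptide masses,
b/y fragment ladders with sulfenic-acid neutral loss, and cross-linked
pair masses.

The central chemistry: CID cleaves the C-S bond adjacent to the sulfoxide
in the linker bridge, splitting an interlinked peptide pair into one
peptide carrying an *alkene* remnant (the NHS-ester / lysine side) and one
carrying a *sulfenic acid* remnant (the second side), which typically
dehydrates to the more stable *thiol* (sulfenic - H2O).  The two remnant
masses sum exactly to the intact bridge addition, so the MS2 fragment pair
reconstructs the precursor mass -- the signature exploited downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ElementalFormula",
    "Moiety",
    "CrosslinkerSpec",
    "Mod",
    "ModifiedPeptide",
    "parse_formula",
    "mono_mass",
    "peptide_mass",
    "mz",
    "neutral_from_mz",
    "fragment_ions",
    "crosslinked_pair_mass",
    "LINKERS",
    "get_linker",
    "register_linker",
    "linker_from_dict",
    "PROTON",
    "WATER",
    "VARIABLE_MODS",
    "RESIDUE_MASSES",
]

# Monoisotopic atomic masses, IUPAC (most abundant isotope).
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON = 1.00728
WATER = 18.010565

# Monoisotopic residue masses of the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# Variable modifications allowed by the search (delta masses, Da).
VARIABLE_MODS: dict[str, tuple[str, float]] = {
    # name: (residue or terminus it applies to, delta mass)
    "carbamidomethyl": ("C", 57.021464),
    "oxidation": ("M", 15.994915),
    "acetyl_protein_nterm": ("nterm", 42.010565),
    "pyroglu": ("Q", -17.026549),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count mapping restricted to C, H, N, O, S."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty formula")
        for el, n in self.counts.items():
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        if all(n == 0 for n in self.counts.values()):
            raise ValueError("formula has no atoms")

    @property
    def mono_mass(self) -> float:
        return mono_mass(self)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}"
            for el, n in self.counts.items()
            if n > 0
        )


def parse_formula(text: str) -> ElementalFormula:
    """Parse an elemental formula string like ``"C7H13NO2S"``.

    An omitted count means 1.  Only C, H, N, O, S are accepted.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula: {text!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise ValueError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula: {text!r}")
    return ElementalFormula(counts)


def mono_mass(f: ElementalFormula) -> float:
    """Monoisotopic mass (Da) of an elemental formula."""
    return sum(ELEMENT_MASSES[el] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class Moiety:
    """A cross-linker remnant left on a peptide after C-S bond cleavage."""

    name: str  # alkene | sulfenic | thiol
    formula: ElementalFormula

    def __post_init__(self) -> None:
        if self.name not in ("alkene", "sulfenic", "thiol"):
            raise ValueError(f"unknown moiety kind: {self.name}")

    @property
    def mono_mass(self) -> float:
        return self.formula.mono_mass


ALL_RESIDUES = frozenset(RESIDUE_MASSES)


@dataclass(frozen=True)
class CrosslinkerSpec:
    """A cleavable cross-linker: reactive ends, remnants, geometry.

    ``end_a`` is the amine-reactive NHS-ester end (lysines); ``end_b`` is
    the second end -- lysines again for the symmetric DSSO, every residue
    for the photoactivated diazirine end of the SDASO series.
    """

    name: str
    end_a_targets: frozenset[str]
    end_b_targets: frozenset[str]
    alkene: Moiety
    sulfenic: Moiety
    thiol: Moiety
    symmetric: bool
    spacer_len: float  # Angstrom
    max_ca_ca: float  # Angstrom, Calpha-Calpha restraint

    def __post_init__(self) -> None:
        d = self.sulfenic.mono_mass - self.thiol.mono_mass
        if abs(d - WATER) > 1e-6:
            raise ValueError(
                f"{self.name}: thiol must be sulfenic - H2O (got delta {d:.6f})"
            )

    @property
    def bridge_mass(self) -> float:
        """Intact bridge mass addition for an interlink (alkene + sulfenic)."""
        return self.alkene.mono_mass + self.sulfenic.mono_mass

    @property
    def deadend_mass(self) -> float:
        """Mass addition for a dead-end (one end hydrolyzed): bridge + H2O."""
        return self.bridge_mass + WATER

    def moiety(self, name: str) -> Moiety:
        try:
            return {"alkene": self.alkene, "sulfenic": self.sulfenic,
                    "thiol": self.thiol}[name]
        except KeyError:
            raise ValueError(f"unknown moiety {name!r}") from None


def _mk(name: str, sulfenic: str, thiol: str, *, symmetric: bool,
        end_b: frozenset[str], spacer: float, max_ca: float) -> CrosslinkerSpec:
    return CrosslinkerSpec(
        name=name,
        end_a_targets=frozenset("K"),
        end_b_targets=end_b,
        alkene=Moiety("alkene", parse_formula("C3H2O")),
        sulfenic=Moiety("sulfenic", parse_formula(sulfenic)),
        thiol=Moiety("thiol", parse_formula(thiol)),
        symmetric=symmetric,
        spacer_len=spacer,
        max_ca_ca=max_ca,
    )


#: Registry of the four built-in linkers.
LINKERS: dict[str, CrosslinkerSpec] = {
    "DSSO": _mk("DSSO", "C3H4O2S", "C3H2SO", symmetric=True,
                end_b=frozenset("K"), spacer=10.1, max_ca=30.0),
    "SDASO-L": _mk("SDASO-L", "C7H13NO2S", "C7H11NOS", symmetric=False,
                   end_b=ALL_RESIDUES, spacer=12.5, max_ca=35.0),
    "SDASO-M": _mk("SDASO-M", "C5H10OS", "C5H8S", symmetric=False,
                   end_b=ALL_RESIDUES, spacer=10.2, max_ca=30.0),
    "SDASO-S": _mk("SDASO-S", "C4H8OS", "C4H6S", symmetric=False,
                   end_b=ALL_RESIDUES, spacer=7.7, max_ca=30.0),
}


def get_linker(name: str) -> CrosslinkerSpec:
    try:
        return LINKERS[name]
    except KeyError:
        raise ValueError(
            f"unknown linker {name!r}; registered: {sorted(LINKERS)}"
        ) from None


def register_linker(spec: CrosslinkerSpec, *, overwrite: bool = False) -> None:
    if spec.name in LINKERS and not overwrite:
        raise ValueError(f"linker {spec.name!r} already registered")
    LINKERS[spec.name] = spec


def linker_from_dict(d: Mapping) -> CrosslinkerSpec:
    """Build a linker from a structured config block.

    Expected keys: name, alkene, sulfenic, thiol (formula strings),
    end_a_targets, end_b_targets (residue strings or "all"), symmetric,
    spacer_len, max_ca_ca.
    """
    def targets(v) -> frozenset[str]:
        if v == "all":
            return ALL_RESIDUES
        return frozenset(v)

    return CrosslinkerSpec(
        name=d["name"],
        end_a_targets=targets(d.get("end_a_targets", "K")),
        end_b_targets=targets(d["end_b_targets"]),
        alkene=Moiety("alkene", parse_formula(d["alkene"])),
        sulfenic=Moiety("sulfenic", parse_formula(d["sulfenic"])),
        thiol=Moiety("thiol", parse_formula(d["thiol"])),
        symmetric=bool(d.get("symmetric", False)),
        spacer_len=float(d["spacer_len"]),
        max_ca_ca=float(d["max_ca_ca"]),
    )


@dataclass(frozen=True)
class Mod:
    """A positioned modification: 1-based residue position, name, delta Da."""

    position: int
    name: str
    mass: float


@dataclass(frozen=True)
class ProteinRef:
    accession: str
    start: int  # 1-based position of the peptide's first residue


_REMNANT_NAMES = frozenset({"alkene", "sulfenic", "thiol"})


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with positioned modifications; the unit of MS3 identification."""

    sequence: str
    mods: tuple[Mod, ...] = ()
    protein_ref: ProteinRef | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - ALL_RESIDUES
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        for m in self.mods:
            if not (1 <= m.position <= n):
                raise ValueError(
                    f"mod position {m.position} outside [1, {n}]")
        remnants = [m for m in self.mods if m.name in _REMNANT_NAMES]
        # one interlink remnant per constituent; an intralink carries
        # alkene + thiol on the same chain, which is the one exception
        if len(remnants) > 2 or (
            len(remnants) == 2
            and {m.name for m in remnants} != {"alkene", "thiol"}
        ):
            raise ValueError("at most one cross-link remnant per constituent "
                             "(alkene+thiol allowed for intralinks)")

    @property
    def mass(self) -> float:
        return peptide_mass(self)

    @property
    def remnant(self) -> Mod | None:
        """The (first) cross-link remnant mod, if any."""
        for m in self.mods:
            if m.name in _REMNANT_NAMES:
                return m
        return None

    def site_in_protein(self, position: int) -> int | None:
        """Map a 1-based peptide position to protein coordinates."""
        if self.protein_ref is None:
            return None
        return self.protein_ref.start + position - 1


def peptide_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification masses."""
    try:
        m = sum(RESIDUE_MASSES[r] for r in p.sequence)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None
    return m + WATER + sum(mod.mass for mod in p.mods)


def mz(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass at charge z: (M + z * proton) / z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def neutral_from_mz(mz_value: float, z: int) -> float:
    """Invert :func:`mz`: neutral mass from an observed m/z and charge."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return mz_value * z - z * PROTON


def fragment_ions(
    p: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    neutral_loss: bool = False,
) -> list[tuple[str, float]]:
    """Theoretical b/y fragment ladder as (label, neutral mass) pairs.

    ``b_i`` covers residues 1..i (with mods in range); ``y_j`` covers the
    C-terminal j residues plus water.  With ``neutral_loss``, every
    fragment containing a sulfenic moiety also emits its dehydrated
    companion 18.010565 Da lower -- sulfenic converts to thiol alongside
    backbone fragmentation during MS3.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    series = set(series)
    unknown = series - {"b", "y"}
    if unknown:
        raise ValueError(f"unsupported ion series: {sorted(unknown)}")

    prefix = [0.0] * (n + 1)
    for i, r in enumerate(p.sequence, start=1):
        prefix[i] = prefix[i - 1] + RESIDUE_MASSES[r]
    mod_prefix = [0.0] * (n + 1)
    sulfenic_at = [False] * (n + 1)
    for i in range(1, n + 1):
        mod_prefix[i] = mod_prefix[i - 1]
        sulfenic_at[i] = sulfenic_at[i - 1]
    for m in p.mods:
        for i in range(m.position, n + 1):
            mod_prefix[i] += m.mass
            if m.name == "sulfenic":
                sulfenic_at[i] = True

    total_mods = mod_prefix[n]
    any_sulfenic = sulfenic_at[n]
    out: list[tuple[str, float]] = []
    for i in range(1, n):
        if "b" in series:
            mass_b = prefix[i] + mod_prefix[i]
            out.append((f"b{i}", mass_b))
            if neutral_loss and sulfenic_at[i]:
                out.append((f"b{i}-H2O", mass_b - WATER))
        if "y" in series:
            j = n - i
            mass_y = (prefix[n] - prefix[i]) + (total_mods - mod_prefix[i]) + WATER
            out.append((f"y{j}", mass_y))
            if neutral_loss and any_sulfenic and not sulfenic_at[i]:
                out.append((f"y{j}-H2O", mass_y - WATER))
    return out


def crosslinked_pair_mass(
    alpha: ModifiedPeptide, beta: ModifiedPeptide, linker: CrosslinkerSpec
) -> float:
    """Neutral mass of an interlinked peptide pair.

    The peptides are passed without remnants (the bridge implies them):
    M = m(alpha) + m(beta) + alkene + sulfenic.
    """
    for p, side in ((alpha, "alpha"), (beta, "beta")):
        if p.remnant is not None:
            raise ValueError(f"{side} peptide must not carry a remnant mod")
    return alpha.mass + beta.mass + linker.bridge_mass
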