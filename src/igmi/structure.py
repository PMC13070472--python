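"""Domain types for protein complexes, mutations and samples, plus PDB I/O.

The package models mutation effects on two-sided protein complexes: every
structure carries a *partner split*, a partition of its chains into the two
interacting sides.  Only heavy atoms of the twenty canonical amino acids are
kept; hydrogens, waters and ligands are dropped at parse time.

Sign convention used throughout the package: ΔΔG = ΔG_mut - ΔG_wt in
kcal/mol, so *negative* values are affinity-enhancing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import (AMINO_ACIDS, CA_CB_BOND, HEAVY_ATOMS, ONE_TO_THREE,
                        THREE_TO_ONE)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ComplexStructure",
    "MutationSpec",
    "SampleRecord",
    "PdbParseError",
    "parse_pdb",
    "write_pdb",
    "parse_mutation_code",
    "get_cbeta",
]


class PdbParseError(ValueError):
    """Raised when PDB-format text cannot be interpreted."""


@dataclass
class AtomRecord:
    """A heavy atom: PDB atom name, element symbol and coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.element.upper() in ("H", "D"):
            raise ValueError("hydrogen atoms are not stored")


@dataclass
class ResidueRecord:
    """One amino-acid residue with its heavy atoms.

    ``complete`` is True when the backbone N, CA and C atoms are all present;
    incomplete residues are kept in the structure but excluded from
    modeling.
    """

    chain_id: str
    resseq: int
    icode: str
    aa: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid type {self.aa!r}")
        if len(self.chain_id) != 1:
            raise ValueError("chain_id must be a single character")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.key}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    @property
    def complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.key} has no atom {name!r}")
        return a.coords


@dataclass
class ComplexStructure:
    """Ordered residues of a two-sided protein complex.

    ``partner_split`` partitions the chain ids into the two interacting
    groups; it defaults to {first chain} vs. {all other chains}.
    """

    residues: list[ResidueRecord]
    partner_split: tuple[frozenset[str], frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a ComplexStructure needs at least one residue")
        self.residues = sorted(self.residues, key=lambda r: r.key)
        chains = self.chain_ids
        if self.partner_split is None:
            self.partner_split = (frozenset({chains[0]}),
                                  frozenset(chains[1:]))
        g1, g2 = (frozenset(self.partner_split[0]), frozenset(self.partner_split[1]))
        if g1 & g2:
            raise ValueError("partner groups must be disjoint")
        if (g1 | g2) != set(chains):
            raise ValueError("partner groups must cover all chains")
        self.partner_split = (g1, g2)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def partner_of(self, chain_id: str) -> int:
        """0 or 1: which side of the interface a chain belongs to."""
        if chain_id in self.partner_split[0]:
            return 0
        if chain_id in self.partner_split[1]:
            return 1
        raise KeyError(f"chain {chain_id!r} not in structure")

    def partner_labels(self) -> np.ndarray:
        """Per-residue side indicator (0/1) in residue order."""
        return np.array([self.partner_of(r.chain_id) for r in self.residues])

    def find(self, chain_id: str, resseq: int, icode: str = "") -> int | None:
        """Index of a residue by author numbering, or None."""
        for i, r in enumerate(self.residues):
            if r.chain_id == chain_id and r.resseq == resseq and r.icode == icode:
                return i
        return None

    def with_partner_split(self, group1, group2) -> "ComplexStructure":
        return ComplexStructure(list(self.residues),
                                (frozenset(group1), frozenset(group2)))


_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A point mutation ``<wtAA><chain><resseq><mutAA>``, e.g. ``AE315C``."""

    wt_aa: str
    chain_id: str
    resseq: int
    mut_aa: str

    def __post_init__(self) -> None:
        for aa, what in ((self.wt_aa, "wild-type"), (self.mut_aa, "mutant")):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{what} amino acid {aa!r} is not canonical")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"wild-type and mutant type are both {self.wt_aa!r}")

    @property
    def code(self) -> str:
        return f"{self.wt_aa}{self.chain_id}{self.resseq}{self.mut_aa}"

    def reversed(self) -> "MutationSpec":
        """The inverse substitution (mutant back to wild type)."""
        return MutationSpec(self.mut_aa, self.chain_id, self.resseq, self.wt_aa)


def parse_mutation_code(code: str) -> MutationSpec:
    """Parse a mutation code like ``"AE315C"`` (Ala at chain E 315 → Cys)."""
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise ValueError(f"malformed mutation code {code!r}; "
                         "expected <AA><chain><position><AA>")
    wt, chain, pos, mut = m.groups()
    return MutationSpec(wt, chain, int(pos), mut)


@dataclass
class SampleRecord:
    """A (wild-type, mutant, mutations, experimental ΔΔG) data point."""

    wt: ComplexStructure
    mut: ComplexStructure
    mutations: list[MutationSpec]
    ddg: float

    def __post_init__(self) -> None:
        if not self.mutations:
            raise ValueError("a sample needs at least one mutation")
        for spec in self.mutations:
            for struct, aa, which in ((self.wt, spec.wt_aa, "wild-type"),
                                      (self.mut, spec.mut_aa, "mutant")):
                idx = struct.find(spec.chain_id, spec.resseq)
                if idx is None:
                    raise ValueError(f"mutation {spec.code}: site not present "
                                     f"in the {which} structure")
                if struct.residues[idx].aa != aa:
                    raise ValueError(
                        f"mutation {spec.code}: {which} structure has "
                        f"{struct.residues[idx].aa!r} at the site, expected {aa!r}")

    def reversed(self) -> "SampleRecord":
        """Swap wild-type/mutant, invert mutation codes, negate the label."""
        return SampleRecord(self.mut, self.wt,
                            [m.reversed() for m in self.mutations], -self.ddg)


# -- PDB I/O ---------------------------------------------------------------

def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _check_coordinate_fields(source: str) -> None:
    for lineno, line in enumerate(source.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PdbParseError(
                        f"malformed coordinate field on line {lineno}: "
                        f"{line[lo:hi]!r}") from None


def parse_pdb(source: str) -> ComplexStructure:
    """Read PDB-format text into a :class:`ComplexStructure`.

    Heavy atoms of standard amino acids only; alternate locations are
    resolved to the highest-occupancy conformer (ties: first in file);
    residues missing backbone N/CA/C are kept but flagged incomplete.
    """
    _check_coordinate_fields(source)
    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as err:
        raise PdbParseError(f"gemmi could not read PDB text: {err}") from err
    if len(st) == 0:
        raise PdbParseError("no model in PDB text")
    residues: list[ResidueRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                continue  # waters, ligands, non-standard residues
            best: dict[str, tuple[float, int, AtomRecord]] = {}
            for order, atom in enumerate(res):
                el = atom.element.name.upper() if atom.element else _element_of(atom.name)
                if el in ("H", "D"):
                    continue
                rec = AtomRecord(atom.name, el,
                                 np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev[0]:
                    best[atom.name] = (atom.occ, order, rec)
            if not best:
                continue
            atoms = [rec for _, _, rec in sorted(
                best.values(), key=lambda t: t[1])]
            # canonical atom order: known names first in table order
            canon = {n: i for i, n in enumerate(HEAVY_ATOMS.get(one, ()))}
            atoms.sort(key=lambda a: (canon.get(a.name, len(canon)), a.name))
            icode = res.seqid.icode.strip()
            residues.append(ResidueRecord(chain.name[:1] or "A",
                                          res.seqid.num, icode, one, atoms))
    if not residues:
        raise PdbParseError("no standard residues in PDB text")
    return ComplexStructure(residues)


def write_pdb(structure: ComplexStructure) -> str:
    """Serialize a structure as fixed-column PDB ATOM records.

    Round-trips through :func:`parse_pdb` up to the 1e-3 Å precision of the
    PDB coordinate fields.
    """
    lines: list[str] = []
    serial = 1
    prev_chain: str | None = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        res3 = ONE_TO_THREE[res.aa]
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res3:>3s} {res.chain_id}"
                f"{res.resseq:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def get_cbeta(residue: ResidueRecord) -> np.ndarray:
    """Cβ coordinates of a residue, in Å.

    Returns the stored CB atom when present; otherwise (glycine, or a
    truncated side chain) an idealized virtual Cβ is constructed from the
    backbone with tetrahedral geometry and a 1.522 Å Cα-Cβ bond.  The
    construction uses cross products only, so it is equivariant under rigid
    motions.
    """
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coords
    if not residue.complete:
        raise ValueError(f"residue {residue.key} lacks backbone atoms; "
                         "cannot build a virtual Cβ")
    n = residue.coords("N")
    ca = residue.coords("CA")
    c = residue.coords("C")
    n1 = n - ca
    n2 = c - ca
    ln1, ln2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if ln1 < 1e-3 or ln2 < 1e-3:
        raise ValueError(f"residue {residue.key}: degenerate backbone")
    n1, n2 = n1 / ln1, n2 / ln2
    w = np.cross(n1, n2)
    lw = np.linalg.norm(w)
    if lw < 1e-3:
        raise ValueError(f"residue {residue.key}: collinear N, CA, C")
    w /= lw
    u = n1 + n2
    u /= np.linalg.norm(u)
    # direction d = -a*u + b*w with the N-CA-CB and C-CA-CB angles both equal
    # to the tetrahedral angle (109.47 deg): d.n1 = -a*(u.n1) = cos(109.47).
    cos_t = -1.0 / 3.0
    a = -cos_t / float(u @ n1)
    b = np.sqrt(max(1.0 - a * a, 0.0))
    d = -a * u + b * w
    return ca + CA_CB_BOND * d / np.linalg.norm(d)
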