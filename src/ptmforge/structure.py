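"""Hierarchical protein model with PDB reading/writing and site addressing.

The model is deliberately small: a :class:`Protein` holds ordered
:class:`Chain` objects, each holding ordered :class:`Residue` objects, each
holding ordered :class:`Atom` objects.  Coordinates are stored in Angstrom
(PDB native); conversion to nm happens only at force-field-facing
boundaries.  Residue numbering is taken verbatim from the file, never
renumbered.

Sites are addressed with the compact string syntax ``"A:CYS155"`` (chain,
optional three-letter residue name, residue number); the residue name may
be omitted, as in ``"A:155"``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Protein",
    "SiteSelector",
    "PDBParseError",
    "SiteFormatError",
    "SiteNotFoundError",
    "SiteMismatchError",
    "read_pdb",
    "write_pdb",
    "parse_site",
    "format_site",
    "find_residue",
]


class PDBParseError(ValueError):
    """A fixed-column PDB record could not be interpreted."""


class SiteFormatError(ValueError):
    """A site string does not follow the ``chain:RESnumber`` syntax."""


class SiteNotFoundError(KeyError):
    """No residue matches the requested (chain, number)."""


class SiteMismatchError(KeyError):
    """A residue exists at the requested number but its name differs."""


@dataclass
class Atom:
    """A single atom: name, element, Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: non-finite position")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.altloc, self.hetero)


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def coordinates(self, names: Optional[Iterable[str]] = None) -> np.ndarray:
        if names is None:
            return np.array([a.position for a in self.atoms], dtype=float)
        return np.array([self.atom(n).position for n in names], dtype=float)

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.id} has no residue {number}{insertion_code}")

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class Protein:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c, r in self.iter_residues():
            for a in r.atoms:
                yield c, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def copy(self) -> "Protein":
        return Protein([c.copy() for c in self.chains], self.title)


@dataclass(frozen=True)
class SiteSelector:
    """Address of one residue: chain label, optional name, residue number."""

    chain: str
    resname: Optional[str]
    resnum: int

    def __post_init__(self) -> None:
        if self.resnum <= 0:
            raise ValueError("residue number must be positive")


_SITE_RE = re.compile(r"^([A-Za-z0-9]):([A-Za-z]{3})?(\d+)$")


def parse_site(spec: str) -> SiteSelector:
    """Parse ``"A:CYS155"`` or ``"A:155"`` into a :class:`SiteSelector`."""
    if not spec:
        raise SiteFormatError("empty site string")
    m = _SITE_RE.match(spec.strip())
    if m is None:
        raise SiteFormatError(
            f"bad site {spec!r}: expected 'chain:RESnumber' like 'A:CYS155' or 'A:155'")
    chain, resname, resnum = m.groups()
    return SiteSelector(chain, resname.upper() if resname else None, int(resnum))


def format_site(site: SiteSelector) -> str:
    return f"{site.chain}:{site.resname or ''}{site.resnum}"


def find_residue(protein: Protein, site: Union[SiteSelector, str]) -> Residue:
    """Return the unique residue matching ``site``.

    Raises :class:`SiteNotFoundError` if nothing sits at (chain, number) and
    :class:`SiteMismatchError` if a residue is there but under another name.
    """
    if isinstance(site, str):
        site = parse_site(site)
    if not protein.has_chain(site.chain):
        raise SiteNotFoundError(f"no chain {site.chain!r}")
    chain = protein.chain(site.chain)
    for r in chain.residues:
        if r.number == site.resnum:
            if site.resname is not None and r.name != site.resname:
                raise SiteMismatchError(
                    f"residue {site.chain}:{site.resnum} is {r.name}, not {site.resname}")
            return r
    raise SiteNotFoundError(f"no residue {site.resnum} in chain {site.chain!r}")


# --- PDB fixed-column I/O ------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, str, str, int, str]:
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed record on line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        element = _guess_element(name)
    atom = Atom(name=name, element=element.capitalize(),
                position=np.array([x, y, z]), occupancy=occupancy,
                altloc=altloc, hetero=line.startswith("HETATM"))
    return atom, resname, chain_id, resnum, icode


def _resolve_altlocs(residue: Residue) -> None:
    """Keep the highest-occupancy altloc variant per atom name (ties: first)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in residue.atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    for name in order:
        best[name].altloc = ""
    residue.atoms = [best[n] for n in order]


def read_pdb(source: Union[str, TextIO]) -> Protein:
    """Read ATOM/HETATM records from a PDB text stream or string.

    Chains/residues keep file order; altloc duplicates collapse to the
    highest-occupancy copy; HETATM records are retained with
    ``Atom.hetero`` set.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    protein = Protein()
    current: Optional[Residue] = None
    current_key: Optional[tuple[str, int, str]] = None
    for lineno, line in enumerate(source, start=1):
        rec = line[:6]
        if rec == "TITLE ":
            protein.title = (protein.title + " " + line[10:].strip()).strip()
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        atom, resname, chain_id, resnum, icode = _parse_atom_record(line, lineno)
        if not protein.has_chain(chain_id):
            protein.chains.append(Chain(chain_id))
        chain = protein.chain(chain_id)
        key = (chain_id, resnum, icode)
        if key != current_key:
            if current is not None:
                _resolve_altlocs(current)
            current = Residue(resname, resnum, icode)
            chain.residues.append(current)
            current_key = key
        current.atoms.append(atom)
    if current is not None:
        _resolve_altlocs(current)
    if not protein.chains:
        raise PDBParseError("no ATOM/HETATM records found")
    return protein


def _format_atom_name(name: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} longer than 4 characters")
    # Standard convention: names starting in column 14 unless 4 chars or
    # two-letter element.
    if len(name) == 4:
        return name
    return f" {name:<3s}"


def write_pdb(protein: Protein) -> str:
    """Emit fixed-column ATOM/HETATM records, TER between chains, END."""
    if not protein.chains or protein.n_atoms == 0:
        raise ValueError("cannot write an empty protein")
    lines: list[str] = []
    if protein.title:
        lines.append(f"TITLE     {protein.title}")
    serial = 1
    for chain in protein.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms:
                rec = "HETATM" if atom.hetero else "ATOM  "
                x, y, z = atom.position
                lines.append(
                    f"{rec}{serial:>5d} {_format_atom_name(atom.name)}"
                    f"{atom.altloc or ' '}{res.name:>3s} {chain.id}"
                    f"{res.number:>4d}{res.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element.upper():>2s}")
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:>5d}      {last.name:>3s} {chain.id}"
                f"{last.number:>4d}{last.insertion_code or ' '}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
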