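"""Residue template library and structure-editing operations.

This module provides the registry of post-translational modifications
reachable through :func:`modify`, a library of residue templates (standard
amino acids, PTMed cysteines such as S-nitrosocysteine, modification
products, and the ACE/NME capping groups), and the editing operations:

* :func:`mutate` — swap a residue for another library residue, keeping the
  backbone fixed and rebuilding the side chain from the template;
* :func:`modify` — apply a named chemical reaction (e.g. ``nitrosylation``)
  to a residue, appending the new moiety via NERF and renaming the residue
  to its product code;
* :func:`prepend` / :func:`append` — grow a chain at either terminus
  (including ACE/NME capping), defaulting to the extended beta-strand
  conformation;
* :func:`build_dipeptide` — the capped ACE-XXX-NME construct used for
  parameterization, in the alpha-helix (phi, psi = -60, -45) or beta-strand
  (-135, 135) conformation.

Side-chain placement always ends with a clash scan: chi1/chi2 are stepped
in 30-degree increments (12 x 12 grid, chi1 in the outer loop, both
starting from the template values); the first clash-free combination wins,
otherwise the least-clashing conformation is kept and a warning is issued.

Templates are heavy-atom only; protonation is delegated to external tools,
so hydrogens present on an edited residue are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import (InternalCoordinate, bond_angle, detect_bonds, dihedral,
                       count_clashes, measure_internal, nerf_place,
                       rotate_about_axis, superpose)
from .structure import (Atom, Chain, Protein, Residue, SiteSelector,
                        find_residue, parse_site)

__all__ = [
    "ResidueTemplate",
    "ModificationRule",
    "get_template",
    "available_templates",
    "list_modifications",
    "modification_rule",
    "RegistryError",
    "ClashWarning",
    "mutate",
    "modify",
    "prepend",
    "append",
    "build_dipeptide",
    "BETA_STRAND",
    "ALPHA_HELIX",
    "PTM_CYSTEINE_CODES",
]

#: Default backbone conformations (phi, psi) in degrees.
BETA_STRAND = (-135.0, 135.0)
ALPHA_HELIX = (-60.0, -45.0)

#: Trans-amide geometry used when growing chains (paper-independent standard).
PEPTIDE_BOND = dict(c_n=1.329, ca_c_n=116.2, c_n_ca=121.7, n_ca=1.458,
                    ca_c=1.525, n_ca_c=111.2, c_o=1.231, ca_c_o=120.8,
                    omega=180.0)

#: The ten PTMed cysteine codes available to mutate.
PTM_CYSTEINE_CODES = ("SNC", "CSS", "SMC", "XCN", "CSO", "CSD", "OCS", "QCS",
                      "CGL", "IYY")


class RegistryError(ValueError):
    """(residue, reaction) pair is not an available modification."""


class ClashWarning(UserWarning):
    """No clash-free rotamer was found; the least-clashing one was kept."""


@dataclass(frozen=True)
class AtomRecipe:
    name: str
    element: str
    refs: tuple[Optional[str], Optional[str], Optional[str]]
    r: Optional[float]
    theta: Optional[float]
    phi: Optional[float]


@dataclass
class ResidueTemplate:
    """Build recipe for one residue: ordered atoms with internal coordinates.

    ``roles`` maps backbone roles (N, CA, C, O) to atom names so capping
    groups with nonstandard rosters (ACE's CH3, NME's methyl C) can be
    positioned by the chain builder.
    """

    code: str
    atoms: list[AtomRecipe] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)
    chis: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def backbone_names(self) -> set[str]:
        return set(self.roles.values())

    def sidechain_names(self) -> list[str]:
        bb = self.backbone_names
        return [a.name for a in self.atoms if a.name not in bb]

    def build(self) -> Residue:
        """Construct the reference residue in its own frame via NERF."""
        coords: dict[str, np.ndarray] = {}
        for k, rec in enumerate(self.atoms):
            if k == 0:
                coords[rec.name] = np.zeros(3)
            elif k == 1:
                prev = rec.refs[2]
                coords[rec.name] = coords[prev] + np.array([rec.r, 0.0, 0.0])
            elif k == 2:
                _, b, c = rec.refs
                th = np.deg2rad(rec.theta)
                coords[rec.name] = coords[c] + rec.r * np.array(
                    [np.cos(np.pi - th), np.sin(np.pi - th), 0.0])
            else:
                a, b, c = rec.refs
                coords[rec.name] = nerf_place(
                    coords[a], coords[b], coords[c],
                    InternalCoordinate(rec.r, rec.theta, rec.phi))
        res = Residue(self.code, 1)
        res.atoms = [Atom(r.name, r.element, coords[r.name])
                     for r in self.atoms]
        return res


def _parse_template(text: str) -> ResidueTemplate:
    tpl = ResidueTemplate(code="")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "residue":
            tpl.code = parts[1]
        elif parts[0] == "role":
            tpl.roles[parts[1]] = parts[2]
        elif parts[0] == "atom":
            name, element = parts[1], parts[2]
            refs = tuple(None if p == "." else p for p in parts[3:6])
            nums = [None if p == "." else float(p) for p in parts[6:9]]
            tpl.atoms.append(AtomRecipe(name, element, refs, *nums))
        elif parts[0].startswith("chi"):
            tpl.chis.append(tuple(parts[1:5]))
    if not tpl.code or not tpl.atoms:
        raise ValueError("malformed residue template")
    return tpl


@lru_cache(maxsize=None)
def get_template(code: str) -> ResidueTemplate:
    """Load a residue template by three-letter code (case-insensitive)."""
    code = code.upper()
    path = resources.files("ptmforge.data.templates").joinpath(f"{code}.tpl")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no residue template for {code!r}") from None
    return _parse_template(text)


def available_templates() -> list[str]:
    files = resources.files("ptmforge.data.templates")
    return sorted(p.name[:-4] for p in files.iterdir()
                  if p.name.endswith(".tpl"))


# --- modification registry -----------------------------------------------

@dataclass(frozen=True)
class ModificationRule:
    target_residue: str
    reaction: str
    product_template: str


# The (amino acid, reaction) registry; reaction names are stored in
# lower case exactly as tabulated, with parenthetical synonyms as aliases.
_REGISTRY: dict[tuple[str, str], str] = {
    ("ARG", "methylation"): "NMM",
    ("ARG", "symmetric demethylation"): "2MR",
    ("ARG", "asymmetric demethylation"): "DA2",
    ("ARG", "phosphorylation"): "RGP",
    ("ASP", "phosphorylation"): "PHD",
    ("CYS", "carbamylation"): "QCS",
    ("CYS", "cyanylation"): "XCN",
    ("CYS", "cysteinylation"): "IYY",
    ("CYS", "glutathionylation"): "CGL",
    ("CYS", "methylation"): "SMC",
    ("CYS", "nitrosylation"): "SNC",
    ("CYS", "phosphorylation"): "CSP",
    ("CYS", "sulfenylation"): "CSO",
    ("CYS", "sulfhydration"): "CSS",
    ("CYS", "sulfinylation"): "CSD",
    ("CYS", "sulfonylation"): "OCS",
    ("GLU", "methylation"): "GME",
    ("HIS", "methylation"): "MHS",
    ("HIS", "phosphorylation"): "NEP",
    ("LYS", "acetylation"): "ALY",
    ("LYS", "methylation"): "MLZ",
    ("LYS", "dimethylation"): "MLY",
    ("LYS", "trimethylation"): "M3L",
    ("LYS", "phosphorylation"): "KZP",
    ("SER", "phosphorylation"): "SEP",
    ("THR", "phosphorylation"): "TPO",
    ("TYR", "phosphorylation"): "PTR",
}

#: Reactions modify accepts beyond the tabulated registry.  Side-chain
#: O-acetylation of serine is supported for completeness even though the
#: registry table lists only phosphorylation for SER.
_EXTRAS: dict[tuple[str, str], str] = {
    ("SER", "acetylation"): "OAS",
}

_ALIASES = {
    "carbamoylation": "carbamylation",
    "nitrosation": "nitrosylation",
    "symmetric dimethylation": "symmetric demethylation",
    "asymmetric dimethylation": "asymmetric demethylation",
}


def _canonical_reaction(reaction: str) -> str:
    reaction = reaction.strip().lower()
    return _ALIASES.get(reaction, reaction)


def list_modifications(residue: Optional[str] = None) -> list[tuple[str, str]]:
    """The (amino acid, reaction) pairs accessible through :func:`modify`.

    With ``residue`` given, only that residue's reactions are returned (an
    empty list for residues with no tabulated modification).
    """
    pairs = sorted(_REGISTRY)
    if residue is not None:
        residue = residue.upper()
        return [p for p in pairs if p[0] == residue]
    return pairs


def modification_rule(residue: str, reaction: str) -> ModificationRule:
    residue = residue.upper()
    reaction = _canonical_reaction(reaction)
    product = _REGISTRY.get((residue, reaction)) or _EXTRAS.get((residue, reaction))
    if product is None:
        valid = [r for (t, r) in list_modifications(residue)]
        raise RegistryError(
            f"no {reaction!r} modification for {residue}; valid reactions: "
            f"{', '.join(valid) if valid else '(none)'}")
    return ModificationRule(residue, reaction, product)


# --- clash-driven rotamer scan -------------------------------------------

def _residue_bond_graph(residue: Residue) -> dict[str, set[str]]:
    bonds = detect_bonds(residue.atoms)
    names = residue.atom_names
    graph: dict[str, set[str]] = {n: set() for n in names}
    for i, j in bonds:
        graph[names[i]].add(names[j])
        graph[names[j]].add(names[i])
    return graph


def _downstream_atoms(graph: dict[str, set[str]], axis: tuple[str, str]) -> list[str]:
    """Atoms reachable from axis[1] without crossing axis[0] (excl. axis)."""
    p, q = axis
    seen = {p, q}
    stack = [q]
    moving: list[str] = []
    while stack:
        for nxt in graph[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                moving.append(nxt)
                stack.append(nxt)
    return moving


def _set_chi(residue: Residue, chi: tuple[str, str, str, str],
             graph: dict[str, set[str]], value: float) -> None:
    a, b, c, d = chi
    current = dihedral(*(residue.atom(n).position for n in chi))
    delta = value - current
    if abs(delta) < 1e-12:
        return
    p = residue.atom(b).position
    q = residue.atom(c).position
    for name in _downstream_atoms(graph, (b, c)):
        atom = residue.atom(name)
        atom.position = rotate_about_axis(atom.position[None, :], p, q - p,
                                          delta)[0]


def _chi_scan(protein: Protein, residue: Residue, template: ResidueTemplate,
              candidate_names: Sequence[str]) -> None:
    """30-degree chi1/chi2 grid scan minimizing clashes, in place.

    chi1 is the outer loop; both torsions start from the template (current)
    values and step +30 degrees; the first clash-free combination is kept.
    """
    chis = [chi for chi in template.chis[:2]
            if all(residue.has_atom(n) for n in chi)]
    candidates = [residue.atom(n) for n in candidate_names
                  if residue.has_atom(n)]

    def clashes() -> int:
        return count_clashes(protein, candidates, exclude_residues=[residue])

    if not chis or not candidates:
        return
    if clashes() == 0:
        return
    graph = _residue_bond_graph(residue)
    base = [dihedral(*(residue.atom(n).position for n in chi)) for chi in chis]
    grid1 = [base[0] + 30.0 * i for i in range(12)]
    grid2 = [base[1] + 30.0 * j for j in range(12)] if len(chis) > 1 else [None]
    best: Optional[tuple[int, float, Optional[float]]] = None
    for v1 in grid1:
        _set_chi(residue, chis[0], graph, v1)
        for v2 in grid2:
            if v2 is not None:
                _set_chi(residue, chis[1], graph, v2)
            n = clashes()
            if n == 0:
                return
            if best is None or n < best[0]:
                best = (n, v1, v2)
    # no clash-free rotamer: restore the least-clashing combination
    _set_chi(residue, chis[0], graph, best[1])
    if best[2] is not None:
        _set_chi(residue, chis[1], graph, best[2])
    warnings.warn(
        f"no clash-free chi1/chi2 rotamer for {residue.name}{residue.number}; "
        f"keeping the least-clashing conformation ({best[0]} clashes)",
        ClashWarning, stacklevel=3)


def _strip_hydrogens(residue: Residue) -> None:
    residue.atoms = [a for a in residue.atoms if a.element.capitalize() != "H"]


# --- mutate / modify ------------------------------------------------------

def mutate(protein: Protein, site: Union[str, SiteSelector],
           new_residue: str) -> Protein:
    """Replace the residue at ``site`` with ``new_residue`` from the library.

    Backbone atoms (N, CA, C, O) keep their coordinates; the side chain is
    rebuilt from the template by superposing the template backbone, aligning
    the beta-carbon direction, and scanning chi1/chi2 for clashes.
    """
    template = get_template(new_residue)  # KeyError if unknown
    out = protein.copy()
    residue = find_residue(out, site)
    if residue.name == template.code:
        return out
    for role in ("N", "CA", "C"):
        if not residue.has_atom(role):
            raise ValueError(
                f"residue {residue.name}{residue.number} lacks backbone atom {role}")
    _strip_hydrogens(residue)
    ref = template.build()
    bb = ("N", "CA", "C")
    transform, _ = superpose(ref.coordinates(bb), residue.coordinates(bb))
    old_cb = residue.atom("CB").position.copy() if residue.has_atom("CB") else None
    backbone = {n: residue.atom(n) for n in ("N", "CA", "C", "O")
                if residue.has_atom(n)}
    new_atoms: list[Atom] = []
    for name in template.atom_names:
        if name in backbone:
            new_atoms.append(backbone[name])
        else:
            src = ref.atom(name)
            new_atoms.append(Atom(name, src.element,
                                  transform.apply(src.position[None, :])[0]))
    residue.atoms = new_atoms
    residue.name = template.code
    # align the beta-carbon direction with the original side chain
    if old_cb is not None and residue.has_atom("CB"):
        ca = residue.atom("CA").position
        u_old = old_cb - ca
        u_new = residue.atom("CB").position - ca
        axis = np.cross(u_new, u_old)
        norm = np.linalg.norm(axis)
        if norm > 1e-8:
            angle = bond_angle(old_cb, ca, residue.atom("CB").position)
            side = [n for n in template.sidechain_names()
                    if residue.has_atom(n)]
            pts = rotate_about_axis(residue.coordinates(side), ca, axis, angle)
            for n, p in zip(side, pts):
                residue.atom(n).position = p
    _chi_scan(out, residue, template, template.sidechain_names())
    return out


def modify(protein: Protein, site: Union[str, SiteSelector],
           reaction: str) -> Protein:
    """Apply a named chemical reaction to the residue at ``site``.

    Existing heavy atoms are retained; atoms the product template adds are
    placed via NERF from the template recipe; the residue is renamed to the
    product code and the chi1/chi2 clash scan is run on the added moiety.
    """
    out = protein.copy()
    residue = find_residue(out, site)
    rule = modification_rule(residue.name, reaction)
    template = get_template(rule.product_template)
    _strip_hydrogens(residue)
    added: list[str] = []
    for rec in template.atoms:
        if residue.has_atom(rec.name):
            continue
        if any(r is None for r in rec.refs):
            raise ValueError(
                f"cannot place {rec.name} of {template.code}: seed atom missing")
        a, b, c = (residue.atom(r).position for r in rec.refs)
        pos = nerf_place(a, b, c, InternalCoordinate(rec.r, rec.theta, rec.phi))
        residue.atoms.append(Atom(rec.name, rec.element, pos))
        added.append(rec.name)
    residue.name = template.code
    _chi_scan(out, residue, template, added)
    return out


# --- chain growth ---------------------------------------------------------

def _place_sidechain(residue: Residue, template: ResidueTemplate) -> None:
    """Fill in side-chain atoms from the template recipe via NERF."""
    for rec in template.atoms:
        if residue.has_atom(rec.name) or rec.name in template.backbone_names:
            continue
        a, b, c = (residue.atom(r).position for r in rec.refs)
        pos = nerf_place(a, b, c, InternalCoordinate(rec.r, rec.theta, rec.phi))
        residue.atoms.append(Atom(rec.name, rec.element, pos))


def _role_atom(residue: Residue, template: ResidueTemplate, role: str) -> Atom:
    return residue.atom(template.roles.get(role, role))


def prepend(protein: Protein, chain: str, residue: str,
            phi: Optional[float] = None, psi: Optional[float] = None) -> Protein:
    """Add a residue before the first residue of ``chain``.

    ``phi`` is the backbone torsion of the existing first residue (used to
    orient the new carbonyl); ``psi`` is the torsion of the new residue.
    Both default to the extended beta-strand conformation.  On an empty
    protein (or missing chain) a fresh one-residue chain is created.
    """
    template = get_template(residue)
    phi = BETA_STRAND[0] if phi is None else phi
    psi = BETA_STRAND[1] if psi is None else psi
    out = protein.copy()
    if not out.has_chain(chain):
        out.chains.append(Chain(chain))
    ch = out.chain(chain)
    if not ch.residues:
        new = template.build()
        new.number = 1
        ch.residues.append(new)
        return out
    first = ch.residues[0]
    first_tpl_roles = {"N": "N", "CA": "CA", "C": "C"}
    try:
        n1 = first.atom(first_tpl_roles["N"]).position
        ca1 = first.atom(first_tpl_roles["CA"]).position
        c1 = first.atom(first_tpl_roles["C"]).position
    except KeyError:
        raise ValueError(f"chain {chain}: first residue lacks backbone atoms")
    geo = PEPTIDE_BOND
    new = Residue(template.code, first.number - 1)
    # carbonyl C of the new residue, oriented by the neighbor's phi torsion
    c_name = template.roles.get("C", "C")
    ca_name = template.roles.get("CA", "CA")
    c0 = nerf_place(c1, ca1, n1,
                    InternalCoordinate(geo["c_n"], geo["c_n_ca"], phi))
    ca0 = nerf_place(ca1, n1, c0,
                     InternalCoordinate(geo["ca_c"], geo["ca_c_n"],
                                        geo["omega"]))
    new.atoms.append(Atom(c_name, "C", c0))
    new.atoms.append(Atom(ca_name, "C", ca0))
    if "O" in template.roles or template.roles.get("O") is None:
        o_name = template.roles.get("O", "O")
        if any(r.name == o_name for r in template.atoms):
            o0 = nerf_place(ca1, n1, c0,
                            InternalCoordinate(geo["c_o"], 123.0, 0.0))
            new.atoms.append(Atom(o_name, "O", o0))
    n_name = template.roles.get("N")
    if n_name is not None and any(r.name == n_name for r in template.atoms):
        n0 = nerf_place(n1, c0, ca0,
                        InternalCoordinate(geo["n_ca"], geo["n_ca_c"], psi))
        new.atoms.append(Atom(n_name, "N", n0))
    _place_sidechain(new, template)
    ch.residues.insert(0, new)
    _chi_scan(out, new, template, template.sidechain_names())
    return out


def append(protein: Protein, chain: str, residue: str,
           phi: Optional[float] = None, psi: Optional[float] = None) -> Protein:
    """Add a residue after the last residue of ``chain`` (C-terminal growth).

    ``psi`` is the backbone torsion of the existing last residue; ``phi`` is
    the torsion of the new residue.  Defaults are the beta-strand values.
    """
    template = get_template(residue)
    phi = BETA_STRAND[0] if phi is None else phi
    psi = BETA_STRAND[1] if psi is None else psi
    out = protein.copy()
    if not out.has_chain(chain):
        out.chains.append(Chain(chain))
    ch = out.chain(chain)
    if not ch.residues:
        new = template.build()
        new.number = 1
        ch.residues.append(new)
        return out
    last = ch.residues[-1]
    n_prev = last.atom("N").position
    ca_prev = last.atom("CA").position
    c_prev = last.atom("C").position
    geo = PEPTIDE_BOND
    new = Residue(template.code, last.number + 1)
    n_name = template.roles.get("N", "N")
    ca_name = template.roles.get("CA", "CA")
    n_new = nerf_place(n_prev, ca_prev, c_prev,
                       InternalCoordinate(geo["c_n"], geo["ca_c_n"], psi))
    ca_new = nerf_place(ca_prev, c_prev, n_new,
                        InternalCoordinate(geo["n_ca"], geo["c_n_ca"],
                                           geo["omega"]))
    new.atoms.append(Atom(n_name, "N", n_new))
    new.atoms.append(Atom(ca_name, "C", ca_new))
    c_name = template.roles.get("C")
    if c_name is not None and any(r.name == c_name for r in template.atoms):
        c_new = nerf_place(c_prev, n_new, ca_new,
                           InternalCoordinate(geo["ca_c"], geo["n_ca_c"], phi))
        new.atoms.append(Atom(c_name, "C", c_new))
        o_name = template.roles.get("O", "O")
        if any(r.name == o_name for r in template.atoms):
            # carbonyl O anti to the (eventual) next amide nitrogen
            o_new = nerf_place(n_new, ca_new, c_new,
                               InternalCoordinate(geo["c_o"], geo["ca_c_o"],
                                                  BETA_STRAND[1] - 180.0))
            new.atoms.append(Atom(o_name, "O", o_new))
    _place_sidechain(new, template)
    # fix the previous residue's carbonyl O anti to the new amide N
    if last.has_atom("O"):
        o_prev = nerf_place(n_prev, ca_prev, c_prev,
                            InternalCoordinate(geo["c_o"], geo["ca_c_o"],
                                               psi - 180.0))
        last.atom("O").position = o_prev
    ch.residues.append(new)
    _chi_scan(out, new, template, template.sidechain_names())
    return out


def build_dipeptide(residue_code: str, conformation: str = "beta") -> Protein:
    """ACE-XXX-NME capped dipeptide with fixed (phi, psi).

    ``conformation`` is ``"alpha"`` (-60, -45) or ``"beta"`` (-135, 135).
    """
    try:
        phi, psi = {"alpha": ALPHA_HELIX, "beta": BETA_STRAND}[conformation]
    except KeyError:
        raise ValueError("conformation must be 'alpha' or 'beta'") from None
    protein = Protein()
    protein = prepend(protein, chain="A", residue=residue_code)
    protein = prepend(protein, chain="A", residue="ACE", phi=phi)
    protein = append(protein, chain="A", residue="NME", psi=psi)
    # renumber 1..3 for readability (fresh construct, no file numbering)
    for i, res in enumerate(protein.chain("A").residues, start=1):
        res.number = i
    return protein
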