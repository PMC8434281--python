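"""Light-weight atomic-structure model with PDB/mmCIF input and PDB output.

Coordinates are in Angstrom throughout; residues carry author numbering
(with insertion codes), which is the public identifier everywhere in the
pipeline.  Hydrogen atoms are dropped on read: crystal structures rarely
contain them and every hydrogen needed downstream is built geometrically.

Alternate locations are resolved deterministically to a single conformer
(highest occupancy, ties broken by the alphabetically first altloc tag).
Only the first model of multi-model files is kept.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "write_structure",
    "resolution_filter",
    "fetch_structure",
]


@dataclass
class Atom:
    """A heavy atom: PDB-convention name, element symbol and position (A)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for {self.name}")


@dataclass
class Residue:
    """A residue (or heteroatom group such as ZN / HOH) with unique atom names."""

    name: str
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name!r} not found in {self.name} {self.chain_id}{self.seq_number}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.name}{self.seq_number}{self.insertion_code}"


@dataclass
class Structure:
    """Parsed atomic model: ordered residues grouped by chain."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    method: str | None = None

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            yield from self.chains.get(chain_id, [])
            return
        for residues in self.chains.values():
            yield from residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


_HYDROGEN = {"H", "D"}


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first tag."""
    by_name: dict[str, list[Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        best.altloc = ""
        out.append(best)
    return out


def read_structure(path: str | os.PathLike, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read.
    fmt:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension).

    Waters and heteroatoms (including Zn ions) are retained; hydrogens are
    dropped; altlocs are resolved to a single conformer; only the first
    model of multi-model entries is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc

    out = Structure(id=(st.name or path.stem).lower())
    res = st.resolution
    out.resolution = float(res) if res and res > 0 else None
    try:
        out.method = st.meta.experiments[0].method or None
    except Exception:
        out.method = None

    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            raw = []
            for at in res:
                if at.element.name.upper() in _HYDROGEN:
                    continue
                raw.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
            if not raw:
                continue
            residues.append(
                Residue(
                    name=res.name,
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(raw),
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.seq_number, r.insertion_code))
            out.chains[chain.name] = residues
    return out


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_structure(s: Structure, path: str | os.PathLike) -> None:
    """Serialize a :class:`Structure` to PDB format (3-decimal coordinates)."""
    if not s.chains or all(not r for r in s.chains.values()):
        raise ValueError("refusing to write an empty structure")
    lines = []
    if s.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {s.resolution:5.2f} ANGSTROMS.")
    serial = 0
    for chain_id, residues in s.chains.items():
        for res in residues:
            hetero = res.name not in _STANDARD_AA and res.name != "AIB"
            record = "HETATM" if hetero else "ATOM  "
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise ValueError(f"atom name {atom.name!r} longer than 4 characters")
                serial += 1
                # PDB column rules: 4-char names start at col 13, shorter at 14
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.position
                lines.append(
                    f"{record}{serial:5d} {name}{'':1s}{res.name:>3s} "
                    f"{chain_id[:1]}{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element.upper():>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {residues[-1].name:>3s} "
                     f"{chain_id[:1]}{residues[-1].seq_number:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def resolution_filter(structures: list[Structure], max_res: float) -> list[Structure]:
    """Keep X-ray entries at resolution <= ``max_res`` (boundary inclusive).

    Entries without resolution metadata (e.g. NMR models) are excluded.
    """
    if max_res <= 0:
        raise ValueError("max_res must be positive")
    return [s for s in structures if s.resolution is not None and s.resolution <= max_res]


def fetch_structure(pdb_id: str, cache_dir: str | os.PathLike) -> Path:
    """Download an mmCIF entry by 4-character ID into ``cache_dir``.

    Purely a convenience for interactive use; nothing in the pipeline or the
    test-suite calls this implicitly.
    """
    import urllib.request

    pdb_id = pdb_id.lower()
    if len(pdb_id) != 4:
        raise ValueError("PDB IDs have four characters")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{pdb_id}.cif"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
        urllib.request.urlretrieve(url, dest)
    return dest
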