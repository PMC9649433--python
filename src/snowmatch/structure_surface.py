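"""Solvent-accessible surface area of protein structures.

Implements the Shrake-Rupley rolling-probe quadrature: each atom is covered
with a deterministic set of test points on an inflated sphere of radius
(r_vdw + r_probe); a point is exposed when it lies outside every neighbouring
atom's inflated sphere, and the atom's SASA is the exposed fraction of the
sphere area.  Per-residue SASA is the sum over the residue's atoms and is
normalised to relative solvent accessibility (RSA) by the residue's
theoretical maximum accessible area.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_N_POINTS = 960

_STANDARD_AA3 = {k.upper() for k in protein_letters_3to1}


def _load_table(name: str) -> list[dict]:
    with resources.files("snowmatch.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


def load_vdw_radii() -> dict[str, float]:
    """Element -> van der Waals radius (Angstrom), NACCESS-style values."""
    return {row["element"]: float(row["radius"]) for row in _load_table("vdw_radii.csv")}


def load_max_asa() -> dict[str, float]:
    """One-letter amino acid -> theoretical maximum accessible area (A^2)."""
    return {row["one_letter"]: float(row["max_asa"]) for row in _load_table("max_asa.csv")}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_index: int
    residue_name: str  # 3-letter code
    atom_name: str
    position: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")

    @property
    def is_standard(self) -> bool:
        return self.residue_name.upper() in _STANDARD_AA3


@dataclass(frozen=True)
class ResidueSurface:
    chain_id: str
    mature_position: int  # 1-based on the mature-protein grid
    amino_acid: str  # 1-letter
    sasa: float  # A^2
    rsa: float  # sasa / maxASA(amino_acid)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors via the golden-spiral lattice.

    Returns an (n, 3) array of unit vectors.  Purely arithmetic, so repeated
    calls with the same ``n`` are bit-identical.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    i = np.arange(n, dtype=float)
    # offset lattice: z strictly inside (-1, 1) avoids degenerate poles
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack((r * np.cos(theta), r * np.sin(theta), z))
    # renormalise to cancel rounding
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def compute_sasa(
    atoms: Sequence[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom's SASA equals (exposed points / n_points) * 4*pi*(r_vdw+probe)^2.
    """
    if len(atoms) == 0:
        raise ValueError("atoms must be non-empty")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")

    coords = np.array([a.position for a in atoms], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinate")
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius

    n = len(atoms)
    if n > 1:
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        if np.any(d2[np.triu_indices(n, k=1)] < 1e-12):
            warnings.warn("duplicate atom coordinates present", stacklevel=2)

    unit = sphere_points(n_points)
    sasa = np.empty(n, dtype=float)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        # neighbours whose inflated sphere can occlude points of atom i
        reach = radii[i] + radii
        near = np.flatnonzero(np.sum((coords - coords[i]) ** 2, axis=1) < reach**2)
        near = near[near != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in near:
            dj = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= dj > radii[j] ** 2
        sasa[i] = exposed.sum() / n_points * 4.0 * np.pi * radii[i] ** 2
    return sasa


def residue_surfaces(
    atoms: Sequence[AtomRecord],
    atom_sasa: Sequence[float],
    maxasa_table: Mapping[str, float] | None = None,
    strict: bool = False,
) -> list[ResidueSurface]:
    """Aggregate per-atom SASA into per-residue SASA and RSA.

    Residues are keyed by (chain, residue_index) and returned in that order.
    Unknown residue names are skipped with a warning unless ``strict``.
    The ``mature_position`` of the output is the author residue index; callers
    mapping onto a mature-protein grid renumber afterwards.
    """
    if maxasa_table is None:
        maxasa_table = load_max_asa()
    three_to_one = {k.upper(): v for k, v in protein_letters_3to1.items()}

    order: list[tuple[str, int]] = []
    by_res: dict[tuple[str, int], dict] = {}
    for atom, s in zip(atoms, atom_sasa):
        key = (atom.chain_id, atom.residue_index)
        if key not in by_res:
            order.append(key)
            by_res[key] = {"name": atom.residue_name.upper(), "sasa": 0.0}
        by_res[key]["sasa"] += float(s)

    out: list[ResidueSurface] = []
    for key in sorted(order):
        name = by_res[key]["name"]
        one = three_to_one.get(name)
        if one is None or one not in maxasa_table:
            msg = f"residue {name} at {key} not in maxASA table"
            if strict:
                raise KeyError(msg)
            logger.warning("%s; skipped", msg)
            continue
        sasa = by_res[key]["sasa"]
        out.append(
            ResidueSurface(
                chain_id=key[0],
                mature_position=key[1],
                amino_acid=one,
                sasa=sasa,
                rsa=sasa / maxasa_table[one],
            )
        )
    return out


class StructureSequenceMismatch(ValueError):
    """Reference sequence does not align to the structure chain."""


class ChainSelectionError(ValueError):
    """No suitable heavy chain could be resolved."""


def atoms_from_pdb(path, vdw_radii: Mapping[str, float] | None = None) -> list[AtomRecord]:
    """Read ATOM records from a PDB file.

    HETATM records, waters, ions and hydrogens are ignored; only the first
    altloc of each atom is kept.  Radii are assigned per element.
    """
    if vdw_radii is None:
        vdw_radii = load_vdw_radii()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " ":
                continue  # HETATM / water
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                element = (atom.element or atom.get_name()[0]).upper()
                if element == "H":
                    continue
                radius = vdw_radii.get(element)
                if radius is None:
                    logger.warning("unknown element %s; skipped", element)
                    continue
                records.append(
                    AtomRecord(
                        chain_id=chain.id,
                        residue_index=residue.id[1],
                        residue_name=residue.get_resname(),
                        atom_name=atom.get_name(),
                        position=tuple(map(float, atom.coord)),
                        vdw_radius=radius,
                    )
                )
    return records


def _chain_sequence(atoms: Iterable[AtomRecord], chain_id: str) -> tuple[str, list[int]]:
    """Observed 1-letter sequence of one chain plus author residue indices."""
    three_to_one = {k.upper(): v for k, v in protein_letters_3to1.items()}
    seen: dict[int, str] = {}
    for a in atoms:
        if a.chain_id != chain_id or a.residue_index in seen:
            continue
        one = three_to_one.get(a.residue_name.upper())
        if one is not None:
            seen[a.residue_index] = one
    indices = sorted(seen)
    return "".join(seen[i] for i in indices), indices


def _global_align(ref: str, obs: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner.align(ref, obs)[0]


def profile_from_structure(
    pdb_path,
    reference_sequence: str,
    heavy_chain: str = "auto",
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    min_identity: float = 0.95,
    min_auto_chain_length: int = 80,
) -> dict[int, float]:
    """Per-mature-position RSA profile of the heavy chain of one structure.

    All chains of the structure (bound peptide, light chain) occlude solvent
    during the SASA computation but only the heavy chain contributes profile
    positions.  Returns ``{mature_position (1-based): rsa}``; positions of the
    reference without resolved density are absent from the mapping, never 0.
    """
    atoms = atoms_from_pdb(pdb_path)
    if not atoms:
        raise ChainSelectionError("structure contains no usable ATOM records")

    chains: dict[str, int] = {}
    for a in atoms:
        chains.setdefault(a.chain_id, 0)
    for cid in chains:
        chains[cid] = len({a.residue_index for a in atoms if a.chain_id == cid})
    if heavy_chain == "auto":
        cid, longest = max(chains.items(), key=lambda kv: (kv[1], kv[0]))
        if longest < min_auto_chain_length:
            raise ChainSelectionError(
                f"longest chain has {longest} residues (< {min_auto_chain_length}); "
                "pass heavy_chain explicitly"
            )
        heavy_chain = cid
    elif heavy_chain not in chains:
        raise ChainSelectionError(f"chain {heavy_chain!r} not present in structure")

    sasa = compute_sasa(atoms, probe_radius=probe_radius, n_points=n_points)
    surfaces = residue_surfaces(atoms, sasa)
    rsa_by_index = {
        s.mature_position: s.rsa for s in surfaces if s.chain_id == heavy_chain
    }

    obs_seq, obs_indices = _chain_sequence(atoms, heavy_chain)
    alignment = _global_align(reference_sequence, obs_seq)
    ref_aln, obs_aln = str(alignment[0]), str(alignment[1])

    aligned_cols = sum(1 for r, o in zip(ref_aln, obs_aln) if r != "-" and o != "-")
    matches = sum(1 for r, o in zip(ref_aln, obs_aln) if r == o and r != "-")
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_identity:
        raise StructureSequenceMismatch(
            f"reference/chain identity {identity:.2f} below {min_identity:.2f}"
        )

    profile: dict[int, float] = {}
    ref_pos = 0
    obs_pos = 0
    for r, o in zip(ref_aln, obs_aln):
        if r != "-":
            ref_pos += 1
        if o != "-":
            obs_pos += 1
        if r != "-" and o != "-":
            author_index = obs_indices[obs_pos - 1]
            if author_index in rsa_by_index:
                profile[ref_pos] = rsa_by_index[author_index]
    return profile


def write_surface_table(path, structure_id: str, surfaces: Sequence[ResidueSurface]) -> None:
    """Persist per-residue surfaces as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure_id", "chain", "mature_position", "amino_acid", "sasa", "rsa"])
        for s in surfaces:
            w.writerow([structure_id, s.chain_id, s.mature_position, s.amino_acid,
                        f"{s.sasa:.4f}", f"{s.rsa:.6f}"])
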