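"""Structural annotation of cleavage sites from predicted models.

Given a structure model of the substrate protein (e.g. from a locally
downloaded predicted-structure database, located by accession-keyed
filenames), each residue of the cleavage window is designated loop (L),
helix (H), or beta strand (S), and the solvent-accessible surface area of
the P1 residue is reported in square Angstroms. A window residue missing
from the model yields a '-' placeholder.

The computation sits behind a small backend interface so a different
engine can be plugged in; the reference backend uses biotite's P-SEA
secondary-structure assignment and Shrake–Rupley rolling-probe SASA.
When no backend/model is available the feature degrades gracefully: the
pipeline logs and continues without structural columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np

from .alphabet import DEFAULT_N_NONPRIME, DEFAULT_N_PRIME, PAD
from .knowledgebase import ProteinEntry

logger = logging.getLogger("terminome")

#: helix classes -> H, strand classes -> S, everything else -> L
_SSE_COLLAPSE = {"a": "H", "b": "S", "c": "L"}


@dataclass(frozen=True)
class StructureAnnotation:
    ss_string: str     # over {L, H, S, '-'}, covering the cleavage window
    sasa: float        # P1 residue, square Angstroms
    model_source: str
    window_sasa: tuple[float, ...] = ()


class StructureBackend(Protocol):
    """Backend contract: per-residue SS class and SASA from a model file."""

    def compute(self, model_path: str | Path
                ) -> tuple[dict[int, str], dict[int, float]]:
        """Return (res_id -> {L,H,S}, res_id -> SASA in A^2)."""
        ...


class BiotiteBackend:
    """Reference backend: P-SEA secondary structure + Shrake–Rupley SASA."""

    def __init__(self, probe_radius: float = 1.4, sasa_points: int = 100):
        self.probe_radius = probe_radius
        self.sasa_points = sasa_points

    def _load(self, model_path: str | Path):
        import biotite.structure.io.pdb as pdb
        import biotite.structure.io.pdbx as pdbx

        path = Path(model_path)
        if path.suffix.lower() in (".cif", ".mmcif"):
            f = pdbx.CIFFile.read(str(path))
            from biotite.structure.io.pdbx import get_structure
            arr = get_structure(f, model=1)
        else:
            f = pdb.PDBFile.read(str(path))
            arr = f.get_structure(model=1)
        return arr[~arr.hetero]

    def compute(self, model_path: str | Path
                ) -> tuple[dict[int, str], dict[int, float]]:
        import biotite.structure as struc

        arr = self._load(model_path)
        sse = struc.annotate_sse(arr)
        # annotate_sse is per residue over amino-acid residues
        res_ids = np.unique(arr.res_id)
        ss_map: dict[int, str] = {}
        aa_res_ids = [rid for rid in res_ids]
        for rid, cls in zip(aa_res_ids[:len(sse)], sse):
            ss_map[int(rid)] = _SSE_COLLAPSE.get(str(cls), "L")

        atom_sasa = struc.sasa(arr, probe_radius=self.probe_radius,
                               point_number=self.sasa_points,
                               vdw_radii="Single")
        sasa_map: dict[int, float] = {}
        for rid in res_ids:
            mask = arr.res_id == rid
            vals = atom_sasa[mask]
            sasa_map[int(rid)] = float(np.nansum(vals))
        return ss_map, sasa_map


def annotate_structure(
    entry: ProteinEntry,
    p1: int,
    model_path: str | Path,
    backend: StructureBackend | None = None,
    n_nonprime: int = DEFAULT_N_NONPRIME,
    n_prime: int = DEFAULT_N_PRIME,
) -> StructureAnnotation:
    """Secondary structure and P1 solvent accessibility of a cleavage site.

    Model residue numbering is assumed to match protein positions (true
    for predicted full-length models). Window positions missing from the
    model are reported as '-'.
    """
    if not 1 <= p1 < entry.length:
        raise ValueError(f"p1={p1} out of range [1, {entry.length})")
    backend = backend or BiotiteBackend()
    ss_map, sasa_map = backend.compute(model_path)
    chars = []
    sasas = []
    for pos in range(p1 - n_nonprime + 1, p1 + n_prime + 1):
        if 1 <= pos <= entry.length and pos in ss_map:
            chars.append(ss_map[pos])
            sasas.append(sasa_map.get(pos, float("nan")))
        else:
            chars.append(PAD)
            sasas.append(float("nan"))
    p1_sasa = sasa_map.get(p1, float("nan"))
    return StructureAnnotation(
        ss_string="".join(chars), sasa=float(p1_sasa),
        model_source=str(model_path), window_sasa=tuple(sasas))


def find_model(structures_dir: str | Path, accession: str) -> Path | None:
    """Locate a model file for an accession in a user-configured folder.

    Matches any file whose name contains the accession (covers both
    ``<ACC>.pdb`` and database-style ``AF-<ACC>-F1-model_v4.pdb`` layouts).
    """
    directory = Path(structures_dir)
    if not directory.is_dir():
        return None
    for path in sorted(directory.iterdir()):
        if accession in path.name and path.suffix.lower() in (
                ".pdb", ".cif", ".mmcif"):
            return path
    return None


# ---------------------------------------------------------------------------
# Synthetic model builders (CA traces with ideal geometry) used for tests
# and demonstrations; they are simplified synthetic stand-ins for predicted
# models, not real structures.

def ideal_helix_model(n_residues: int = 20):
    """Synthetic poly-alanine alpha-helix CA trace (biotite AtomArray)."""
    import biotite.structure as struc

    i = np.arange(n_residues)
    coords = np.stack([
        2.3 * np.cos(np.deg2rad(100.0) * i),
        2.3 * np.sin(np.deg2rad(100.0) * i),
        1.5 * i,
    ], axis=1)
    return _ca_array(coords, res_ids=i + 1)


def ideal_strand_pair_model(n_residues: int = 12, separation: float = 4.8):
    """Synthetic two-strand antiparallel-sheet-like CA trace."""
    def strand(z0):
        i = np.arange(n_residues)
        return np.stack([3.3 * i, 0.95 * (-1.0) ** i,
                         np.full(n_residues, z0)], axis=1)

    coords = np.concatenate([strand(0.0), strand(separation)])
    res_ids = np.concatenate([np.arange(1, n_residues + 1),
                              np.arange(n_residues + 1, 2 * n_residues + 1)])
    chains = ["A"] * n_residues + ["B"] * n_residues
    return _ca_array(coords, res_ids=res_ids, chains=chains)


def globular_decoy_model(side: int = 5, spacing: float = 3.8):
    """Synthetic compact 'globule': a cubic lattice of CA pseudo-residues.

    Center residues are buried, corner residues exposed — useful to check
    that SASA orders buried vs. exposed positions correctly.
    """
    grid = np.arange(side, dtype=float) * spacing
    coords = np.array([[x, y, z] for x in grid for y in grid for z in grid])
    return _ca_array(coords, res_ids=np.arange(1, len(coords) + 1))


def _ca_array(coords: np.ndarray, res_ids: np.ndarray,
              chains: list[str] | None = None):
    import biotite.structure as struc

    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = "A" if chains is None else chains
    arr.res_id = np.asarray(res_ids)
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.hetero[:] = False
    return arr


def write_model_pdb(atom_array, path: str | Path) -> Path:
    """Write a synthetic model to PDB for backend round-trips."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(atom_array)
    f.write(str(path))
    return Path(path)
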