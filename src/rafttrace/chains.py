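"""Synthetic acyl-chain conformer ensembles.

Chains of n carbons are built from internal coordinates (fixed bond length
and C–C–C bond angle, per-bond dihedrals) with the standard natural
extension reference frame construction.  Dihedral models:

``all_trans``
    every dihedral 180° — the planar zig-zag of an extended saturated chain;
``rotamer_sampled``
    dihedrals drawn from the rotamer states {trans 180°, gauche ±65°} with
    configurable weights — spans linear to strongly kinked conformations;
``continuous``
    dihedrals uniform on (−180°, 180°].

Setting ``cis_bond_index=j`` pins the dihedral about the C(j)–C(j+1) bond
to 0° (cis), emulating the kink of a monounsaturated chain such as
palmitoleic acid (16:1 cis-9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .ligands import AtomRecord, LigandConformer

__all__ = ["ConformerSpec", "generate_conformers", "build_chain", "write_conformers_pdb"]


@dataclass(frozen=True)
class ConformerSpec:
    """Recipe for a synthetic acyl-chain conformer ensemble (lengths in Å)."""

    n_carbons: int = 16
    bond_length: float = 1.53
    bond_angle: float = 111.5          # degrees, C–C–C
    dihedral_model: str = "rotamer_sampled"   # all_trans | rotamer_sampled | continuous
    rotamer_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)  # trans, g+, g-
    cis_bond_index: Optional[int] = None
    n_conformers: int = 1
    seed: int = 0
    residue_name: str = "PLM"

    def __post_init__(self) -> None:
        if self.n_carbons < 2:
            raise ValueError(f"n_carbons must be >= 2, got {self.n_carbons}")
        if self.bond_length <= 0:
            raise ValueError(f"bond_length must be > 0, got {self.bond_length}")
        if not 0 < self.bond_angle < 180:
            raise ValueError(f"bond_angle must be in (0, 180), got {self.bond_angle}")
        if self.dihedral_model not in ("all_trans", "rotamer_sampled", "continuous"):
            raise ValueError(f"unknown dihedral_model {self.dihedral_model!r}")
        if self.n_conformers < 0:
            raise ValueError("n_conformers must be >= 0")
        if self.cis_bond_index is not None and not (2 <= self.cis_bond_index <= self.n_carbons - 2):
            raise ValueError(
                f"cis_bond_index must lie in [2, {self.n_carbons - 2}] "
                f"for a {self.n_carbons}-carbon chain, got {self.cis_bond_index}")


def build_chain(n: int, bond_length: float, bond_angle_deg: float,
                dihedrals_deg: Sequence[float]) -> np.ndarray:
    """Cartesian coordinates (n × 3, Å) of a carbon chain from internal
    coordinates.  ``dihedrals_deg`` has n − 3 entries; dihedral i governs the
    placement of carbon i + 4 about the C(i+2)–C(i+3) bond.
    """
    if len(dihedrals_deg) != max(n - 3, 0):
        raise ValueError(f"need {n - 3} dihedrals for {n} carbons, got {len(dihedrals_deg)}")
    theta = np.deg2rad(bond_angle_deg)
    xyz = np.zeros((n, 3))
    xyz[1] = (bond_length, 0.0, 0.0)
    if n >= 3:
        xyz[2] = xyz[1] + bond_length * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, n):
        phi = np.deg2rad(dihedrals_deg[i - 3])
        a, b, c = xyz[i - 3], xyz[i - 2], xyz[i - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        normal = np.cross(ab, bc)
        normal /= np.linalg.norm(normal)
        m = np.cross(normal, bc)
        d_local = bond_length * np.array([
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ])
        xyz[i] = c + d_local[0] * bc + d_local[1] * m + d_local[2] * normal
    return xyz


def _draw_dihedrals(spec: ConformerSpec, rng: np.random.Generator) -> np.ndarray:
    n_dih = max(spec.n_carbons - 3, 0)
    if spec.dihedral_model == "all_trans":
        dih = np.full(n_dih, 180.0)
    elif spec.dihedral_model == "rotamer_sampled":
        states = np.array([180.0, 65.0, -65.0])
        weights = np.asarray(spec.rotamer_weights, dtype=float)
        weights = weights / weights.sum()
        dih = states[rng.choice(3, size=n_dih, p=weights)]
    else:
        dih = rng.uniform(-180.0, 180.0, size=n_dih)
    if spec.cis_bond_index is not None and n_dih > 0:
        # dihedral about bond C(j)-C(j+1) is the one placing atom j+2 (1-based)
        dih[spec.cis_bond_index - 2] = 0.0
    return dih


def generate_conformers(spec: ConformerSpec) -> list[LigandConformer]:
    """Generate a reproducible synthetic conformer ensemble.

    Every conformer has exact bond lengths and bond angles; only the
    dihedrals vary according to the dihedral model.  The same spec and seed
    give bitwise-identical coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    conformers = []
    for k in range(spec.n_conformers):
        dih = _draw_dihedrals(spec, rng)
        xyz = build_chain(spec.n_carbons, spec.bond_length, spec.bond_angle, dih)
        atoms = [AtomRecord(name=f"C{i + 1}", element="C",
                            xyz=(xyz[i, 0], xyz[i, 1], xyz[i, 2]))
                 for i in range(spec.n_carbons)]
        conformers.append(LigandConformer(
            source_id=f"synthetic:{spec.dihedral_model}:{k:04d}",
            ligand_code=spec.residue_name, chain="A", res_seq=k + 1, atoms=atoms))
    return conformers


def write_conformers_pdb(conformers: Sequence[LigandConformer],
                         path: str | Path) -> Path:
    """Write conformers as HETATM records, one residue per conformer."""
    structure = gemmi.Structure()
    structure.name = "synthetic-conformers"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for conf in conformers:
        residue = gemmi.Residue()
        residue.name = conf.ligand_code
        residue.seqid = gemmi.SeqId(conf.res_seq, " ")
        residue.het_flag = "H"
        for rec in conf.atoms:
            atom = gemmi.Atom()
            atom.name = rec.name
            atom.element = gemmi.Element(rec.element)
            atom.pos = gemmi.Position(*rec.xyz)
            atom.occ = 1.0
            residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    path.write_text(structure.make_pdb_string())
    return path
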