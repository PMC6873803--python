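"""Fatty-acid ligand extraction, rigid superposition and RMSD densities.

A fatty-acid conformer analysis asks: of all deposited conformers of a
ligand (e.g. palmitic acid, PLM, or palmitoleic acid, PAM), how close is
each to a reference conformer, measured as the RMSD over the acyl-chain
carbon atoms after optimal rigid-body superposition?  Binning those RMSDs
into a fixed number of bins and dividing by the dataset size yields a
normalized occurrence distribution — the probability of being
conformationally close to the reference — and the argmin identifies the
closest deposited conformer.

Superposition is Kabsch-type: least-squares optimal proper rotation plus
translation, no reflection (chirality preserved), no scaling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord", "LigandConformer", "SuperpositionResult", "RMSDDensity",
    "parse_ligands", "superpose_carbons", "rmsd_density", "closest_conformer",
    "LigandParseError", "SuperpositionError",
]

_CARBON_NAME = re.compile(r"^C(\d+)$")


class LigandParseError(ValueError):
    pass


class SuperpositionError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class LigandConformer:
    """One copy of a ligand residue extracted from a PDB-format file."""

    source_id: str
    ligand_code: str
    chain: str
    res_seq: int
    atoms: list[AtomRecord]

    def carbon_names(self) -> list[str]:
        """Chain carbons named C1..Cn, in numeric order."""
        named = [(int(m.group(1)), a.name) for a in self.atoms
                 if (m := _CARBON_NAME.match(a.name)) and a.element.upper() == "C"]
        return [name for _, name in sorted(named)]

    def coords(self, names: Sequence[str]) -> np.ndarray:
        lookup = {a.name: a.xyz for a in self.atoms}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"atoms not present: {missing}")
        return np.array([lookup[n] for n in names], dtype=float)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # 3×3 proper orthogonal
    translation: np.ndarray    # 3-vector, Å
    rmsd: float                # Å
    n_matched: int


@dataclass
class RMSDDensity:
    """20-bin (by default) normalized RMSD occurrence distribution."""

    bin_edges: np.ndarray      # n_bins + 1 edges, Å
    frequencies: np.ndarray    # counts / dataset_size, sums to 1
    n_bins: int
    dataset_size: int
    rmsds: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded: list[str] = field(default_factory=list)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one record per atom name: highest occupancy, ties → first altloc."""
    by_name: dict[str, AtomRecord] = {}
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occupancy, _neg_altloc(atom.altloc)) > (prev.occupancy, _neg_altloc(prev.altloc)):
            by_name[atom.name] = atom
    return list(by_name.values())


def _neg_altloc(altloc: str) -> tuple[int, ...]:
    # higher tuple wins; blank altloc outranks 'A' which outranks 'B', ...
    return tuple(-ord(c) for c in altloc) if altloc else (1,)


def parse_ligands(pdb_text: str, code: str, source: str = "pdb") -> list[LigandConformer]:
    """Extract every copy of residue ``code`` from PDB-format text.

    One conformer is returned per (model, chain, residue number); alternate
    locations are resolved to the highest-occupancy copy (ties: altloc 'A' /
    lexicographically first).  An input without matching residues yields an
    empty list.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise LigandParseError(f"{source}: malformed PDB input: {exc}") from exc
    conformers: list[LigandConformer] = []
    multi_model = len(structure) > 1
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.name != code.upper():
                    continue
                atoms = []
                for atom in residue:
                    element = atom.element.name if atom.element.name != "X" else ""
                    if not element:
                        element = re.sub(r"[^A-Za-z]", "", atom.name)[:1]
                    atoms.append(AtomRecord(
                        name=atom.name,
                        element=element,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        occupancy=atom.occ,
                    ))
                atoms = _resolve_altlocs(atoms)
                sid = f"{source}:{chain.name}:{residue.seqid.num}"
                if multi_model:
                    sid = f"{source}:m{model.num}:{chain.name}:{residue.seqid.num}"
                conformers.append(LigandConformer(
                    source_id=sid, ligand_code=residue.name, chain=chain.name,
                    res_seq=residue.seqid.num, atoms=atoms))
    return conformers


def _matched_coords(mobile: LigandConformer, reference: LigandConformer,
                    matching: Optional[dict[str, str]] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    ref_names = reference.carbon_names()
    if matching is None:
        matching = {n: n for n in ref_names}
    mob_names = set(mobile.carbon_names())
    pairs = [(r, m) for r, m in matching.items() if r in ref_names and m in mob_names]
    if len(pairs) < 3:
        unmatched = [r for r in ref_names if matching.get(r) not in mob_names]
        raise SuperpositionError(
            f"{mobile.source_id}: only {len(pairs)} matched carbon pairs "
            f"(need >= 3); unmatched reference atoms: {unmatched}")
    ref = reference.coords([r for r, _ in pairs])
    mob = mobile.coords([m for _, m in pairs])
    return mob, ref


def superpose_carbons(mobile: LigandConformer, reference: LigandConformer,
                      matching: Optional[dict[str, str]] = None) -> SuperpositionResult:
    """Optimal proper rigid-body superposition of matched chain carbons.

    Carbons are matched by canonical names C1..Cn (identity mapping by
    default, or an explicit reference→mobile name map); conformers missing
    named carbons are matched on the common subset.  Returns the rotation,
    translation and RMSD over the matched pairs.
    """
    mob, ref = _matched_coords(mobile, reference, matching)
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    matrix = rot.as_matrix()
    translation = ref_c - matrix @ mob_c
    rmsd = float(rssd / np.sqrt(len(mob)))
    return SuperpositionResult(rotation=matrix, translation=translation,
                               rmsd=rmsd, n_matched=len(mob))


def rmsd_density(conformers: Sequence[LigandConformer],
                 reference: LigandConformer,
                 n_bins: int = 20,
                 bin_range: Optional[tuple[float, float]] = None) -> RMSDDensity:
    """Normalized RMSD occurrence distribution against a reference conformer.

    Each conformer is rigidly superposed on the reference over the matched
    carbons; RMSDs are histogrammed into ``n_bins`` equal-width bins over
    [0, max RMSD] (or ``bin_range``) and counts are divided by the dataset
    size, so the frequencies sum to one.  Conformers with fewer than three
    matchable carbons are excluded and reported in ``excluded``.
    """
    if len(conformers) == 0:
        raise ValueError("need at least one conformer")
    rmsds, ids, excluded = [], [], []
    for conf in conformers:
        try:
            rmsds.append(superpose_carbons(conf, reference).rmsd)
            ids.append(conf.source_id)
        except SuperpositionError:
            excluded.append(conf.source_id)
    if not rmsds:
        raise SuperpositionError("no conformer could be superposed on the reference")
    rmsds = np.asarray(rmsds)
    if bin_range is None:
        hi = float(rmsds.max())
        bin_range = (0.0, hi if hi > 0 else 1.0)
    counts, edges = np.histogram(rmsds, bins=n_bins, range=bin_range)
    return RMSDDensity(bin_edges=edges, frequencies=counts / len(rmsds),
                       n_bins=n_bins, dataset_size=len(rmsds),
                       rmsds=rmsds, excluded=excluded)


def closest_conformer(conformers: Sequence[LigandConformer],
                      reference: LigandConformer) -> tuple[str, float]:
    """The conformer with the smallest carbon RMSD to the reference.

    Ties are broken by lexicographic source_id.
    """
    if len(conformers) == 0:
        raise ValueError("need at least one conformer")
    best: Optional[tuple[float, str]] = None
    for conf in conformers:
        r = superpose_carbons(conf, reference).rmsd
        key = (r, conf.source_id)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[1], best[0]
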