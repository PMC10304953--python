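"""Protein structure handling: PDB I/O, rigid superposition, patch statistics.

The structural questions addressed here are (i) how similar two small
iron-sulfur protein folds are (optimal rigid superposition of paired CA
atoms, Kabsch algorithm) and (ii) whether a set of residues singled out by
NMR clusters around the 4Fe-4S cofactor more tightly than chance (a
permutation test on the mean nearest-heavy-atom distance to the cluster).

Structures are held as a flat atom table parsed from fixed-column PDB
records; cluster atoms are identified as HETATM records whose residue name
is SF4 or FES by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLUSTER_RESNAMES = ("SF4", "FES")


class PDBFormatError(ValueError):
    pass


@dataclass
class Atom:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    element: str
    record: str  # ATOM or HETATM

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    atoms: list[Atom] = field(default_factory=list)

    def ca_atoms(self) -> list[Atom]:
        return [a for a in self.atoms
                if a.record == "ATOM" and a.atom_name == "CA"]

    def ca_coords(self, residue_range: tuple[int, int] | None = None) -> np.ndarray:
        cas = self.ca_atoms()
        if residue_range is not None:
            lo, hi = residue_range
            cas = [a for a in cas if lo <= a.residue_number <= hi]
        return np.array([a.coord for a in cas]).reshape(-1, 3)

    def cluster_atoms(self, resnames=CLUSTER_RESNAMES) -> list[Atom]:
        return [a for a in self.atoms
                if a.record == "HETATM" and a.residue_name in resnames]

    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.record == "ATOM":
                seen.setdefault(a.residue_number, None)
        return list(seen)

    def heavy_atoms_by_residue(self) -> dict[int, np.ndarray]:
        out: dict[int, list[np.ndarray]] = {}
        for a in self.atoms:
            if a.record == "ATOM" and not a.element.upper().startswith("H"):
                out.setdefault(a.residue_number, []).append(a.coord)
        return {r: np.array(v) for r, v in out.items()}


def read_pdb(path) -> StructureModel:
    """Parse ATOM/HETATM records from a fixed-column PDB file.

    Raises :class:`PDBFormatError` naming the offending line on a malformed
    coordinate field, and on an empty file.
    """
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record not in ("ATOM", "HETATM"):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path}:{lineno}: malformed coordinate field: "
                    f"{line.rstrip()!r}") from exc
            try:
                serial = int(line[6:11])
                resnum = int(line[22:26])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path}:{lineno}: malformed serial/residue number") from exc
            element = line[76:78].strip() or line[12:16].strip()[:1]
            atoms.append(Atom(serial=serial, atom_name=line[12:16].strip(),
                              residue_name=line[17:20].strip(),
                              chain_id=line[21].strip() or "A",
                              residue_number=resnum, x=x, y=y, z=z,
                              element=element, record=record))
    if not atoms:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    return StructureModel(atoms=atoms)


def write_pdb(model: StructureModel, path) -> None:
    """Write fixed-column ATOM/HETATM records (coordinates to 3 decimals)."""
    with open(path, "w") as fh:
        for a in model.atoms:
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"{a.record:<6s}{a.serial:>5d} {name:<4s}{'':1s}"
                f"{a.residue_name:>3s} {a.chain_id:1s}{a.residue_number:>4d}"
                f"{'':4s}{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"{'':10s}{a.element:>2s}\n")
        fh.write("END\n")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper (det = +1)
    translation: np.ndarray   # applied after rotation: b ~ R a + t
    rmsd: float               # A
    n_atoms: int


def kabsch_superpose(coords_a: np.ndarray,
                     coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of paired coordinate sets (Kabsch, SVD).

    Finds the proper rotation R and translation t minimizing
    RMSD(R a + t, b).  Requires equal counts, at least three points, and a
    non-degenerate (non-collinear) configuration.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); "
                         f"got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    rmsd = float(np.sqrt(np.sum((a0 @ rot.T - b0) ** 2) / n))
    trans = cb - rot @ ca
    return SuperpositionResult(rotation=rot, translation=trans,
                               rmsd=rmsd, n_atoms=n)


@dataclass
class PatchTestResult:
    observed: float     # mean nearest-heavy-atom distance to the cluster, A
    p_value: float
    n_permutations: int
    null_mean: float


def patch_statistic(model: StructureModel, residue_set,
                    cluster_resnames=CLUSTER_RESNAMES) -> float:
    """Mean over the set of each residue's minimum heavy-atom distance (A)
    to any cluster atom."""
    cluster = model.cluster_atoms(cluster_resnames)
    if not cluster:
        raise ValueError("no cluster (HETATM SF4/FES) atoms in structure")
    ccoords = np.array([a.coord for a in cluster])
    heavy = model.heavy_atoms_by_residue()
    dists = []
    for r in residue_set:
        if r not in heavy:
            raise ValueError(f"residue {r} absent from structure")
        d = np.linalg.norm(heavy[r][:, None, :] - ccoords[None, :, :], axis=2)
        dists.append(d.min())
    return float(np.mean(dists))


def patch_permutation_test(model: StructureModel, residue_set,
                           B: int = 999, seed: int = 0,
                           cluster_resnames=CLUSTER_RESNAMES) -> PatchTestResult:
    """Permutation test: is the residue set closer to the cluster than chance?

    The null draws uniform same-size residue subsets; the p-value uses the
    add-one estimator p = (1 + #{null <= observed}) / (B + 1), so
    p in [1/(B+1), 1].  Deterministic given ``seed``.
    """
    residue_set = sorted(set(residue_set))
    if len(residue_set) < 2:
        raise ValueError("residue set must contain at least 2 residues")
    if B < 99:
        raise ValueError("need at least 99 permutations")
    all_res = model.residue_numbers()
    observed = patch_statistic(model, residue_set, cluster_resnames)
    rng = np.random.default_rng(seed)
    k = len(residue_set)
    hits = 0
    null_vals = np.empty(B)
    for i in range(B):
        subset = rng.choice(all_res, size=k, replace=False)
        null_vals[i] = patch_statistic(model, subset, cluster_resnames)
        # tolerance so ties (e.g. the same subset in another order) count
        if null_vals[i] <= observed + 1e-9:
            hits += 1
    p = (1 + hits) / (B + 1)
    return PatchTestResult(observed=observed, p_value=float(p),
                           n_permutations=B, null_mean=float(null_vals.mean()))
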