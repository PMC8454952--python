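"""Coarse-grained chains, reference states and CA distance matrices.

A protein is represented by three beads per residue (CA, CB, O); all other
atoms are reconstructed from ideal backbone geometry when needed.  Reference
folds carry a CA-CA distance matrix plus an exclusion mask used to remove
rigid or ambiguous regions (e.g. a non-switching N-terminal domain) from
contact-based order parameters.  Excluded entries are represented internally
as a boolean mask and only materialized as a 99 Å sentinel on export, so no
downstream code compares floats against a magic number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel distance (Å) written for excluded matrix entries on export.
MASK_SENTINEL = 99.0


class StructureError(ValueError):
    """Raised for unusable or inconsistent structural input."""


@dataclass
class CoarseChain:
    """Three-bead-per-residue chain with 1-based contiguous numbering."""

    sequence: str
    ca_xyz: np.ndarray
    cb_xyz: np.ndarray
    o_xyz: np.ndarray
    domain_label: list[str] = field(default_factory=list)
    author_numbering: list[int] = field(default_factory=list)
    virtual_cb: np.ndarray | None = None  # True where CB was reconstructed

    def __post_init__(self) -> None:
        self.ca_xyz = np.asarray(self.ca_xyz, float)
        self.cb_xyz = np.asarray(self.cb_xyz, float)
        self.o_xyz = np.asarray(self.o_xyz, float)
        n = len(self.sequence)
        if not self.domain_label:
            self.domain_label = [""] * n
        if not self.author_numbering:
            self.author_numbering = list(range(1, n + 1))
        if self.virtual_cb is None:
            self.virtual_cb = np.zeros(n, bool)
        for name, arr in (("ca_xyz", self.ca_xyz), ("cb_xyz", self.cb_xyz),
                          ("o_xyz", self.o_xyz)):
            if arr.shape != (n, 3):
                raise StructureError(
                    f"{name} has shape {arr.shape}, expected {(n, 3)}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residue_index(self) -> np.ndarray:
        """1-based contiguous residue numbering."""
        return np.arange(1, self.n_residues + 1)

    def validate(self, physical: bool = True) -> None:
        """Check chain invariants; raise :class:`StructureError` on failure."""
        n = self.n_residues
        if n < 6:
            raise StructureError(f"chain has {n} residues; at least 6 required")
        bad = [aa for aa in self.sequence if aa not in AA1_TO_3]
        if bad:
            raise StructureError(f"unknown residue codes: {sorted(set(bad))}")
        for name, arr in (("CA", self.ca_xyz), ("CB", self.cb_xyz),
                          ("O", self.o_xyz)):
            if not np.all(np.isfinite(arr)):
                raise StructureError(f"non-finite {name} coordinates")
        if physical:
            d = np.linalg.norm(np.diff(self.ca_xyz, axis=0), axis=1)
            if d.size and (d.min() < 2.0 or d.max() > 5.0):
                raise StructureError(
                    f"consecutive CA-CA distances outside [2.0, 5.0] Å "
                    f"(range {d.min():.2f}-{d.max():.2f})")

    def with_coordinates(self, ca: np.ndarray, cb: np.ndarray,
                         o: np.ndarray) -> "CoarseChain":
        return replace(self, ca_xyz=np.array(ca, float),
                       cb_xyz=np.array(cb, float), o_xyz=np.array(o, float))

    def bead_positions(self) -> np.ndarray:
        """Stacked (3n, 3) bead array ordered [all CA | all CB | all O]."""
        return np.vstack([self.ca_xyz, self.cb_xyz, self.o_xyz])

    def with_bead_positions(self, pos: np.ndarray) -> "CoarseChain":
        n = self.n_residues
        pos = np.asarray(pos, float)
        return self.with_coordinates(pos[:n], pos[n:2 * n], pos[2 * n:])

    def subset(self, start: int, stop: int) -> "CoarseChain":
        """Residue range [start, stop] (1-based inclusive) as a new chain."""
        sl = slice(start - 1, stop)
        return CoarseChain(
            sequence=self.sequence[sl],
            ca_xyz=self.ca_xyz[sl].copy(), cb_xyz=self.cb_xyz[sl].copy(),
            o_xyz=self.o_xyz[sl].copy(),
            domain_label=list(self.domain_label[sl]),
            author_numbering=list(self.author_numbering[sl]),
            virtual_cb=self.virtual_cb[sl].copy())


@dataclass
class DistanceMatrix:
    """Symmetric CA-CA distance matrix with an exclusion mask."""

    d: np.ndarray
    mask: np.ndarray | None = None  # True = excluded
    mask_sentinel: float = MASK_SENTINEL

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise StructureError("distance matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(self.d.shape, bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.d.shape:
            raise StructureError("mask shape mismatch")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def materialized(self) -> np.ndarray:
        """Distances with excluded entries set to the sentinel value."""
        out = self.d.copy()
        out[self.mask] = self.mask_sentinel
        return out

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.materialized(), fmt="%.4f", delimiter="\t")

    @classmethod
    def from_tsv(cls, path, sentinel: float = MASK_SENTINEL) -> "DistanceMatrix":
        d = np.loadtxt(path, delimiter="\t")
        mask = d == sentinel
        d = d.copy()
        d[mask] = 0.0
        return cls(d=d, mask=mask, mask_sentinel=sentinel)


@dataclass
class ReferenceState:
    """A named reference fold: chain + (possibly masked) distance matrix."""

    name: str
    chain: CoarseChain
    dmatrix: DistanceMatrix
    source: str = ""

    def __post_init__(self) -> None:
        if self.dmatrix.n != self.chain.n_residues:
            raise StructureError(
                f"distance matrix size {self.dmatrix.n} != chain length "
                f"{self.chain.n_residues}")


def build_distance_matrix(chain: CoarseChain) -> DistanceMatrix:
    """Full symmetric CA-CA distance matrix of a chain (no masking)."""
    ca = chain.ca_xyz
    diff = ca[:, None, :] - ca[None, :, :]
    return DistanceMatrix(d=np.sqrt((diff ** 2).sum(-1)))


def _check_range(r: tuple[int, int], n: int) -> tuple[int, int]:
    a, b = int(r[0]), int(r[1])
    if a < 1 or b > n or a > b:
        raise StructureError(f"malformed residue range {r} for n={n}")
    return a, b


def apply_exclusions(dm: DistanceMatrix,
                     excluded_ranges: list[tuple[tuple[int, int],
                                                 tuple[int, int]]]
                     ) -> DistanceMatrix:
    """Mask residue-pair blocks of a distance matrix.

    Each item is a pair of 1-based inclusive residue ranges ``(ra, rb)``:
    every off-diagonal entry (i, j) with i in ra and j in rb (or vice versa)
    is excluded.  ``ra == rb`` excludes a block's internal pairs.  The
    operation is idempotent and never alters unmasked distances.
    """
    n = dm.n
    mask = dm.mask.copy()
    for ra, rb in excluded_ranges:
        a1, a2 = _check_range(ra, n)
        b1, b2 = _check_range(rb, n)
        block = np.zeros((n, n), bool)
        block[a1 - 1:a2, b1 - 1:b2] = True
        mask |= block | block.T
    np.fill_diagonal(mask, False)
    return DistanceMatrix(d=dm.d.copy(), mask=mask,
                          mask_sentinel=dm.mask_sentinel)


def parse_exclusion_spec(spec: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Parse ``"1-100x1-100,1-100x101-162"`` into range pairs."""
    out = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            continue
        try:
            left, right = item.split("x")
            a1, a2 = (int(x) for x in left.split("-"))
            b1, b2 = (int(x) for x in right.split("-"))
        except ValueError as exc:
            raise StructureError(f"cannot parse exclusion term {item!r}") from exc
        out.append(((a1, a2), (b1, b2)))
    return out


# ---------------------------------------------------------------------------
# PDB input / output (via biotite)
# ---------------------------------------------------------------------------

def load_structure(path, model: int = 1, chain_id: str | None = None) -> CoarseChain:
    """Read one model/chain of a PDB file into a :class:`CoarseChain`.

    Only CA, CB and O atoms are kept; glycine (or any residue missing CB)
    receives a virtual CB from ideal backbone geometry and is flagged as
    such.  Residues missing CA or O are rejected with an error; insertion
    codes are rejected; for alternate locations the first is kept.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdbf = pdb.PDBFile.read(str(path))
    n_models = pdbf.get_model_count()
    if not 1 <= model <= n_models:
        raise StructureError(
            f"model {model} not present (file has {n_models} model(s))")
    atoms = pdbf.get_structure(model=model, altloc="first",
                               extra_fields=["b_factor"])
    chains_present = sorted(set(atoms.chain_id))
    if chain_id is None:
        chain_id = chains_present[0]
    if chain_id not in chains_present:
        raise StructureError(
            f"chain {chain_id!r} not found; file has chains {chains_present}")
    atoms = atoms[atoms.chain_id == chain_id]
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if hasattr(atoms, "ins_code") and np.any(atoms.ins_code != ""):
        raise StructureError("insertion codes are not supported")

    res_ids, res_starts = np.unique(atoms.res_id, return_index=True)
    order = np.argsort(res_starts)
    res_ids = res_ids[order]

    seq, ca, cb, ox, virt, authors = [], [], [], [], [], []
    for rid in res_ids:
        sub = atoms[atoms.res_id == rid]
        res_name = sub.res_name[0]
        one = AA3_TO_1.get(res_name)
        if one is None:
            continue  # skip non-standard residues
        names = list(sub.atom_name)
        if "CA" not in names or "O" not in names:
            raise StructureError(
                f"residue {res_name}{rid} lacks backbone CA/O atoms")
        ca.append(sub.coord[names.index("CA")])
        ox.append(sub.coord[names.index("O")])
        if "CB" in names:
            cb.append(sub.coord[names.index("CB")])
            virt.append(False)
        else:
            cb.append(np.full(3, np.nan))
            virt.append(True)
        seq.append(one)
        authors.append(int(rid))

    if len(seq) < 6:
        raise StructureError(
            f"chain {chain_id!r} has only {len(seq)} complete residues (>= 6 required)")

    ca = np.array(ca, float)
    cb = np.array(cb, float)
    virt = np.array(virt, bool)
    if np.any(virt):
        cb[virt] = geometry.place_virtual_cb(ca)[virt]
    chain = CoarseChain(sequence="".join(seq), ca_xyz=ca, cb_xyz=cb,
                        o_xyz=np.array(ox, float),
                        author_numbering=authors, virtual_cb=virt)
    chain.validate(physical=False)
    return chain


def write_pdb(path, chains: CoarseChain | list[CoarseChain]) -> None:
    """Write one chain, or a list of same-length chains as PDB models."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(chains, CoarseChain):
        chains = [chains]
    n = chains[0].n_residues
    template = chains[0]

    def make_atoms(chain: CoarseChain) -> "struc.AtomArray":
        arr = struc.AtomArray(3 * n)
        coords, names, elements, res_ids, res_names = [], [], [], [], []
        for i in range(n):
            res3 = AA1_TO_3[chain.sequence[i]]
            for name, xyz, elem in (("CA", chain.ca_xyz[i], "C"),
                                    ("CB", chain.cb_xyz[i], "C"),
                                    ("O", chain.o_xyz[i], "O")):
                coords.append(xyz)
                names.append(name)
                elements.append(elem)
                res_ids.append(chain.author_numbering[i])
                res_names.append(res3)
        arr.coord = np.array(coords, float)
        arr.atom_name = np.array(names)
        arr.element = np.array(elements)
        arr.res_id = np.array(res_ids)
        arr.res_name = np.array(res_names)
        arr.chain_id = np.array(["A"] * (3 * n))
        arr.hetero = np.zeros(3 * n, bool)
        return arr

    pdbf = pdb.PDBFile()
    if len(chains) == 1:
        pdbf.set_structure(make_atoms(chains[0]))
    else:
        stack = struc.stack([make_atoms(c) for c in chains])
        pdbf.set_structure(stack)
    del template
    pdbf.write(str(path))
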