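"""The coarse-grained potential.

Five physical term groups act on the three-bead chain:

* ``backbone`` — harmonic virtual bonds (CA-CA, CA-CB, CA-O, O-CA'),
  a flat-bottom chirality penalty on the normalized scalar triple product
  of the local backbone frame (penalizes mirror geometry only), double
  Gaussian basin wells on the (i, i+2)/(i, i+3) CA distances favoring
  helical and extended local geometry, and compact excluded-volume
  repulsion.
* ``contact`` — CB-CB pair wells for |j-i| > 2 with residue-type-dependent
  depths from the packaged 20x20 matrix; a second, longer-range well (at
  40% depth) stands in for water-mediated interactions.
* ``burial`` — each residue's smooth CB-neighbour density scored against
  three overlapping density-class wells with per-type preferences.
* ``hydrogen bonding`` — O···(virtual amide N) wells in helical (i, i+4)
  and sheet registries, plus a cooperative term over ladders of >= 3
  consecutive rungs (shorter ladders contribute exactly zero
  cooperativity, letting 3-residue strands form).
* ``memory`` — the fragment-memory bias: Gaussian wells pulling CA/CB
  distances inside short overlapping sequence windows (3-9 residues)
  toward a reference structure, scaled by lambda_memory (default 0.3).

Two steering terms complete the model: the Q_diff umbrella bias
½ k (Q_diff - Q0)² and a flat-bottom interdomain separation restraint.
All terms depend only on internal coordinates, so every energy is exactly
invariant under rigid motions; analytic forces are validated against
central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from . import geometry, params
from .chain import CoarseChain, ReferenceState, StructureError
from .cv import QdiffSpec, pair_sigma

#: default memory bias scale (the study's raised value; library default 0.2)
LAMBDA_MEMORY = 0.3
#: default umbrella spring constant, kcal/mol per unit Q_diff^2
UMBRELLA_K = 1500.0


@dataclass(frozen=True)
class ModelConstants:
    """Tunable constants of the transferable terms (energies kcal/mol, Å)."""

    bond_k: float = 100.0
    chir_cmin: float = 0.2
    chir_k: float = 10.0
    basin_eps: float = 1.2
    # helical / extended basin centers measured on the ideal builders
    basin_h13: float = 5.399
    basin_s13: float = 0.45
    basin_h14: float = 5.044
    basin_s14: float = 0.55
    basin_e13: float = 6.600
    basin_es13: float = 0.45
    basin_e14: float = 10.078
    basin_es14: float = 0.80
    excl_r_ca: float = 3.6
    excl_r_cb: float = 2.8
    excl_k: float = 10.0
    # single-peaked wells (rise and fall meet) so packed pairs feel a
    # restoring force instead of a flat plateau
    contact_well1: tuple = (4.2, 5.5, 5.5, 7.2)
    contact_well2: tuple = (6.8, 8.2, 8.2, 9.8)
    contact_scale: float = 1.0
    contact_second_scale: float = 0.3
    burial_switch: tuple = (6.0, 8.0)
    burial_beta: float = 1.5
    burial_scale: float = 1.0
    burial_classes_lo: tuple = (-100.0, 2.0, 5.0)
    burial_classes_hi: tuple = (2.0, 5.0, 100.0)
    hb_eps_helix: float = 0.6
    hb_eps_sheet: float = 0.8
    hb_eps_coop: float = 0.6
    hb_sig_on: float = 0.6
    hb_sig_ca: float = 0.8
    # O···N and CA-CA registry centers measured on the ideal builders
    hb_ron_helix: float = 5.907
    hb_rca_helix: float = 6.199
    hb_ron_anti: float = 5.04
    hb_rca_anti: float = 5.16
    hb_min_sep: int = 4
    bead_mass: float = 60.0  # g/mol, uniform over beads


DEFAULT_CONSTANTS = ModelConstants()


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol; total is their sum."""

    backbone: float = 0.0
    contact: float = 0.0
    burial: float = 0.0
    hbond: float = 0.0
    memory: float = 0.0
    umbrella: float = 0.0
    restraint: float = 0.0
    detail: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (self.backbone + self.contact + self.burial + self.hbond
                + self.memory + self.umbrella + self.restraint)

    @classmethod
    def from_components(cls, comps: np.ndarray) -> "EnergyBreakdown":
        return cls(
            backbone=float(comps[K.C_BOND] + comps[K.C_CHIR]
                           + comps[K.C_BASIN] + comps[K.C_EXCL]),
            contact=float(comps[K.C_CONTACT]),
            burial=float(comps[K.C_BURIAL]),
            hbond=float(comps[K.C_HB] + comps[K.C_HBCOOP]),
            memory=float(comps[K.C_MEMORY]),
            umbrella=float(comps[K.C_UMBRELLA]),
            restraint=float(comps[K.C_RESTRAINT]),
            detail={
                "bonds": float(comps[K.C_BOND]),
                "chirality": float(comps[K.C_CHIR]),
                "basin": float(comps[K.C_BASIN]),
                "excluded": float(comps[K.C_EXCL]),
                "hbond_additive": float(comps[K.C_HB]),
                "hbond_cooperative": float(comps[K.C_HBCOOP]),
            })


@dataclass
class MemoryFragment:
    """One local structural bias window (3-9 residues)."""

    start: int              # 1-based first residue of the window
    length: int
    res_i: np.ndarray       # 0-based residue indices of biased pairs
    res_j: np.ndarray
    kind_i: np.ndarray      # 0 = CA, 1 = CB
    kind_j: np.ndarray
    target: np.ndarray      # reference distances, Å
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 3 <= self.length <= 9:
            raise StructureError(
                f"fragment length {self.length} outside [3, 9]")
        if np.any(self.target <= 0):
            raise StructureError("non-positive memory target distance")
        if np.any(np.abs(self.res_j - self.res_i) < 2):
            raise StructureError("memory pairs must be >= 2 residues apart")

    @property
    def n_pairs(self) -> int:
        return len(self.target)


@dataclass
class MemoryLibrary:
    """Fragment-memory biases attached to sequence windows of one chain."""

    fragments: list[MemoryFragment]
    lambda_memory: float = LAMBDA_MEMORY
    covered_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lambda_memory <= 0:
            raise StructureError("lambda_memory must be positive")

    def concat(self, other: "MemoryLibrary") -> "MemoryLibrary":
        """Dual-memory library: both references applied with equal strength."""
        if abs(self.lambda_memory - other.lambda_memory) > 1e-12:
            raise StructureError("cannot concat libraries with different lambda")
        return MemoryLibrary(fragments=self.fragments + other.fragments,
                             lambda_memory=self.lambda_memory,
                             covered_regions=sorted(set(self.covered_regions)
                                                    | set(other.covered_regions)))


def build_memory_library(ref: ReferenceState,
                         regions: list[tuple[int, int]] | None = None,
                         fragment_length: int = 9, stride: int = 1,
                         weight_mode: str = "uniform",
                         weight_scale: float = 1.0,
                         lambda_memory: float = LAMBDA_MEMORY) -> MemoryLibrary:
    """Tile reference regions with overlapping memory windows.

    Windows never span a region boundary, so an uncovered linker breaks the
    continuity of the bias.  A region shorter than ``fragment_length`` gets
    a single clipped window (>= 3 residues).  ``weight_mode='uniform'``
    (default) gives every fragment weight 1, so overlapping windows
    accumulate — the local bias must dominate local geometry for the model
    to fold; ``'coverage'`` instead down-weights fragments by their
    residues' window coverage, yielding a per-residue-normalized (much
    weaker) bias.
    """
    chain = ref.chain
    n = chain.n_residues
    if regions is None:
        regions = [(1, n)]
    windows: list[tuple[int, int]] = []
    for lo, hi in regions:
        if lo < 1 or hi > n or lo > hi:
            raise StructureError(f"region {(lo, hi)} outside chain 1..{n}")
        ln = hi - lo + 1
        if ln < 3:
            raise StructureError(f"region {(lo, hi)} shorter than 3 residues")
        flen = min(fragment_length, ln)
        for s in range(lo, hi - flen + 2, stride):
            windows.append((s, flen))

    coverage = np.zeros(n)
    for s, ln in windows:
        coverage[s - 1:s - 1 + ln] += 1

    fragments = []
    for s, ln in windows:
        res = np.arange(s - 1, s - 1 + ln)
        ri, rj, ki, kj, tgt = [], [], [], [], []
        for a in range(ln):
            for b in range(a + 2, ln):
                i, j = res[a], res[b]
                for kind, coords in ((0, chain.ca_xyz), (1, chain.cb_xyz)):
                    ri.append(i)
                    rj.append(j)
                    ki.append(kind)
                    kj.append(kind)
                    tgt.append(float(np.linalg.norm(coords[i] - coords[j])))
        if weight_mode == "coverage":
            w = weight_scale * float(np.mean(1.0 / coverage[res]))
        elif weight_mode == "uniform":
            w = weight_scale
        else:
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        fragments.append(MemoryFragment(
            start=s, length=ln,
            res_i=np.array(ri, np.int64), res_j=np.array(rj, np.int64),
            kind_i=np.array(ki, np.int64), kind_j=np.array(kj, np.int64),
            target=np.array(tgt), weight=w))
    return MemoryLibrary(fragments=fragments, lambda_memory=lambda_memory,
                         covered_regions=list(regions))


@dataclass
class UmbrellaBias:
    """Harmonic bias ½ k (Q_diff - Q0)² on the dual-reference coordinate."""

    q0: float
    spec: QdiffSpec
    k: float = UMBRELLA_K

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("umbrella spring constant must be positive")
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError(f"umbrella center {self.q0} outside [0, 1]")


@dataclass
class SeparationRestraint:
    """Flat-bottom push-apart restraint between two residue-group centroids."""

    group_a: tuple[int, int]  # 1-based inclusive residue ranges
    group_b: tuple[int, int]
    min_dist: float = 30.0
    k: float = 10.0

    def __post_init__(self) -> None:
        a, b = self.group_a, self.group_b
        if not (a[1] < b[0] or b[1] < a[0]):
            raise StructureError("restraint groups overlap")


class CoarseModel:
    """A chain bound to a compiled parameter set; evaluates energies/forces."""

    def __init__(self, chain: CoarseChain, p: K.ModelParams,
                 constants: ModelConstants):
        self.chain = chain
        self.params = p
        self.constants = constants
        self.n = chain.n_residues

    def energy_forces(self, pos: np.ndarray | None = None
                      ) -> tuple[EnergyBreakdown, np.ndarray, float]:
        """Returns (breakdown, forces (3n, 3) kcal/mol/Å, Q_diff or NaN)."""
        if pos is None:
            pos = self.chain.bead_positions()
        pos = np.ascontiguousarray(pos, float)
        F = np.zeros_like(pos)
        comps, qdiff = K.total_force(pos, F, self.params)
        return EnergyBreakdown.from_components(comps), F, float(qdiff)

    def energy(self, pos: np.ndarray | None = None) -> EnergyBreakdown:
        return self.energy_forces(pos)[0]

    def qdiff(self, pos: np.ndarray | None = None) -> float:
        return self.energy_forces(pos)[2]


def _backbone_arrays(chain: CoarseChain, c: ModelConstants) -> dict:
    n = chain.n_residues
    bi, bj, br0 = [], [], []
    for i in range(n - 1):       # CA-CA virtual bonds
        bi.append(i)
        bj.append(i + 1)
        br0.append(geometry.BOND_CA_CA)
    for i in range(n):           # CA-CB
        bi.append(i)
        bj.append(n + i)
        br0.append(geometry.BOND_CA_CB)
    for i in range(n):           # CA-O
        bi.append(i)
        bj.append(2 * n + i)
        br0.append(geometry.BOND_CA_O)
    for i in range(n - 1):       # O-CA(next)
        bi.append(2 * n + i)
        bj.append(i + 1)
        br0.append(geometry.BOND_O_CA_NEXT)
    bonds = dict(b_i=np.array(bi, np.int64), b_j=np.array(bj, np.int64),
                 b_r0=np.array(br0), b_k=np.full(len(bi), c.bond_k))

    ei, ej, er = [], [], []
    for i in range(n):
        for j in range(i + 2, n):
            ei.append(i)
            ej.append(j)
            er.append(c.excl_r_ca)
            ei.append(n + i)
            ej.append(n + j)
            er.append(c.excl_r_cb)
    excl = dict(e_i=np.array(ei, np.int64), e_j=np.array(ej, np.int64),
                e_r=np.array(er), e_k=c.excl_k)

    mid = np.arange(1, n - 1, dtype=np.int64)
    chir = dict(ch_ia=mid - 1, ch_ib=mid, ch_ic=mid + 1, ch_ig=n + mid,
                ch_cmin=c.chir_cmin, ch_k=c.chir_k)
    basin = dict(ra_i=np.arange(0, n - 3, dtype=np.int64), ra_eps=c.basin_eps,
                 ra_h13=c.basin_h13, ra_s13=c.basin_s13, ra_h14=c.basin_h14,
                 ra_s14=c.basin_s14, ra_e13=c.basin_e13, ra_es13=c.basin_es13,
                 ra_e14=c.basin_e14, ra_es14=c.basin_es14)
    return {**bonds, **excl, **chir, **basin}


def _contact_arrays(chain: CoarseChain, c: ModelConstants) -> dict:
    n = chain.n_residues
    types = params.residue_type_indices(chain.sequence)
    gamma = params.contact_matrix()
    ci, cj, g1 = [], [], []
    for i in range(n):
        for j in range(i + 3, n):
            ci.append(n + i)
            cj.append(n + j)
            g1.append(gamma[types[i], types[j]])
    g1 = c.contact_scale * np.array(g1)
    return dict(c_i=np.array(ci, np.int64), c_j=np.array(cj, np.int64),
                c_g1=g1, c_g2=c.contact_second_scale * g1,
                c_w1=np.array(c.contact_well1), c_w2=np.array(c.contact_well2))


def _burial_arrays(chain: CoarseChain, c: ModelConstants) -> dict:
    types = params.residue_type_indices(chain.sequence)
    gam = c.burial_scale * params.burial_propensities()[types]
    return dict(bu_gam=np.ascontiguousarray(gam),
                bu_lo=np.array(c.burial_classes_lo),
                bu_hi=np.array(c.burial_classes_hi),
                bu_beta=c.burial_beta,
                bu_a=c.burial_switch[0], bu_b=c.burial_switch[1])


def _hbond_fields(c: ModelConstants) -> dict:
    return dict(hb_on=1, hb_eps_h=c.hb_eps_helix, hb_eps_sheet=c.hb_eps_sheet,
                hb_eps_coop=c.hb_eps_coop, hb_ron_h=c.hb_ron_helix,
                hb_sig_on=c.hb_sig_on, hb_rca_h=c.hb_rca_helix,
                hb_sig_ca=c.hb_sig_ca, hb_ron_a=c.hb_ron_anti,
                hb_rca_a=c.hb_rca_anti, hb_min_sep=c.hb_min_sep)


def _memory_arrays(chain: CoarseChain, lib: MemoryLibrary) -> dict:
    n = chain.n_residues
    mi, mj, r0, w = [], [], [], []
    for frag in lib.fragments:
        if np.any(frag.res_j >= n) or np.any(frag.res_i < 0):
            raise StructureError(
                f"fragment at {frag.start} extends beyond the chain")
        mi.append(frag.res_i + n * frag.kind_i)
        mj.append(frag.res_j + n * frag.kind_j)
        r0.append(frag.target)
        w.append(np.full(frag.n_pairs, lib.lambda_memory * frag.weight))
    mi = np.concatenate(mi) if mi else np.zeros(0, np.int64)
    mj = np.concatenate(mj) if mj else np.zeros(0, np.int64)
    r0 = np.concatenate(r0) if r0 else np.zeros(0)
    w = np.concatenate(w) if w else np.zeros(0)
    # overlapping windows bias the same pair toward the same target many
    # times; merging identical (i, j, r0) entries by summing weights is an
    # exact rewrite of the sum and much cheaper to evaluate
    if len(mi):
        key = np.stack([mi.astype(float), mj.astype(float),
                        np.round(r0, 9)], axis=1)
        _, idx, inv = np.unique(key, axis=0, return_index=True,
                                return_inverse=True)
        w_merged = np.zeros(len(idx))
        np.add.at(w_merged, inv, w)
        mi, mj, r0, w = mi[idx], mj[idx], r0[idx], w_merged
    sep = np.abs((mj % n) - (mi % n))
    return dict(m_i=mi.astype(np.int64), m_j=mj.astype(np.int64),
                m_r0=r0, m_sig=pair_sigma(sep), m_w=w)


def _qdiff_arrays(spec: QdiffSpec) -> dict:
    cs = spec.contact_set
    n = cs.n_residues
    return dict(q_i=cs.i.astype(np.int64), q_j=cs.j.astype(np.int64),
                q_rA=np.ascontiguousarray(cs.r_a),
                q_rB=np.ascontiguousarray(cs.r_b),
                q_sig=np.ascontiguousarray(cs.sigma),
                q_qA=float(spec.q_a), q_qB=float(spec.q_b),
                q_norm=1.0 / ((n - 2) * (n - 3)))


def build_model(chain: CoarseChain,
                constants: ModelConstants = DEFAULT_CONSTANTS,
                terms: tuple[str, ...] = ("backbone", "contact", "burial",
                                          "hbond"),
                memory: MemoryLibrary | list[MemoryLibrary] | None = None,
                umbrella: UmbrellaBias | None = None,
                qdiff_spec: QdiffSpec | None = None,
                restraint: SeparationRestraint | None = None) -> CoarseModel:
    """Compile a chain + term selection into an evaluatable model.

    ``qdiff_spec`` (without ``umbrella``) makes the model report Q_diff for
    every evaluation without biasing the dynamics.
    """
    n = chain.n_residues
    p = K.empty_params(n)._asdict()
    unknown = set(terms) - {"backbone", "contact", "burial", "hbond"}
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    if "backbone" in terms:
        p.update(_backbone_arrays(chain, constants))
    if "contact" in terms:
        p.update(_contact_arrays(chain, constants))
    if "burial" in terms:
        p.update(_burial_arrays(chain, constants))
    if "hbond" in terms:
        p.update(_hbond_fields(constants))
    if memory is not None:
        if isinstance(memory, list):
            lib = memory[0]
            for extra in memory[1:]:
                lib = lib.concat(extra)
        else:
            lib = memory
        p.update(_memory_arrays(chain, lib))
    if umbrella is not None:
        p.update(_qdiff_arrays(umbrella.spec))
        p.update(umb_on=1, umb_k=float(umbrella.k), umb_q0=float(umbrella.q0))
    elif qdiff_spec is not None:
        p.update(_qdiff_arrays(qdiff_spec))
    if restraint is not None:
        a, b = restraint.group_a, restraint.group_b
        p.update(r_a=np.arange(a[0] - 1, a[1], dtype=np.int64),
                 r_b=np.arange(b[0] - 1, b[1], dtype=np.int64),
                 r_mind=float(restraint.min_dist), r_k=float(restraint.k))
    return CoarseModel(chain, K.ModelParams(**p), constants)


# ---------------------------------------------------------------------------
# Single-term evaluators (thin wrappers over build_model)
# ---------------------------------------------------------------------------

def _eval(model: CoarseModel) -> tuple[float, np.ndarray, EnergyBreakdown]:
    bd, F, _ = model.energy_forces()
    return bd.total, F, bd


def eval_backbone(chain: CoarseChain,
                  constants: ModelConstants = DEFAULT_CONSTANTS):
    """Backbone energy + forces; sub-terms in the returned breakdown detail."""
    return _eval(build_model(chain, constants, terms=("backbone",)))


def eval_contact(chain: CoarseChain,
                 constants: ModelConstants = DEFAULT_CONSTANTS):
    return _eval(build_model(chain, constants, terms=("contact",)))


def eval_burial(chain: CoarseChain,
                constants: ModelConstants = DEFAULT_CONSTANTS):
    return _eval(build_model(chain, constants, terms=("burial",)))


def eval_hbond(chain: CoarseChain,
               constants: ModelConstants = DEFAULT_CONSTANTS):
    return _eval(build_model(chain, constants, terms=("hbond",)))


def eval_memory(chain: CoarseChain, lib: MemoryLibrary,
                constants: ModelConstants = DEFAULT_CONSTANTS):
    return _eval(build_model(chain, constants, terms=(), memory=lib))


def eval_umbrella(chain: CoarseChain, bias: UmbrellaBias,
                  constants: ModelConstants = DEFAULT_CONSTANTS):
    return _eval(build_model(chain, constants, terms=(), umbrella=bias))


def eval_separation_restraint(chain: CoarseChain, group_a, group_b,
                              min_dist: float = 30.0, k_r: float = 10.0,
                              constants: ModelConstants = DEFAULT_CONSTANTS):
    r = SeparationRestraint(tuple(group_a), tuple(group_b), min_dist, k_r)
    return _eval(build_model(chain, constants, terms=(), restraint=r))


def total_energy(chain: CoarseChain, **kwargs):
    """Full breakdown + forces for the configured model (see build_model)."""
    model = build_model(chain, **kwargs)
    bd, F, qd = model.energy_forces()
    return bd, F, qd


def finite_difference_check(model: CoarseModel, pos: np.ndarray | None = None,
                            h: float = 1e-5, n_probe: int | None = None,
                            seed: int = 0) -> float:
    """Max relative error between analytic forces and central differences.

    With ``n_probe`` set, only a random subset of coordinates is probed
    (cheaper for large systems); otherwise every coordinate is checked.
    """
    if pos is None:
        pos = model.chain.bead_positions()
    pos = np.array(pos, float)
    _, F, _ = model.energy_forces(pos)
    scale = max(np.abs(F).max(), 1.0)
    coords = [(i, d) for i in range(pos.shape[0]) for d in range(3)]
    if n_probe is not None and n_probe < len(coords):
        rng = np.random.default_rng(seed)
        coords = [coords[k] for k in
                  rng.choice(len(coords), n_probe, replace=False)]
    worst = 0.0
    for i, d in coords:
        orig = pos[i, d]
        pos[i, d] = orig + h
        ep = model.energy(pos).total
        pos[i, d] = orig - h
        em = model.energy(pos).total
        pos[i, d] = orig
        f_fd = -(ep - em) / (2 * h)
        worst = max(worst, abs(f_fd - F[i, d]) / scale)
    return worst
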