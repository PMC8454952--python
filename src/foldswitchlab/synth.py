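"""Synthetic structures: ideal helices, beta meanders, fold-switch toy pairs
and random coils.

These generators stand in for deposited experimental structures so that the
whole pipeline (collective variables, energy model, sampling, WHAM,
refolding analysis) is exercisable without downloads.  The central fixture
is :func:`make_toy_foldswitch_pair`: one sequence realized both as an
alpha-helical hairpin (state A) and as an antiparallel beta meander
(state B), optionally fused to a compact anchor domain through a
memory-free 10-residue linker — the toy analog of a fold-switching
C-terminal domain tethered to a rigid N-terminal domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import geometry
from .chain import CoarseChain, DistanceMatrix, ReferenceState, StructureError, \
    apply_exclusions, build_distance_matrix

# Ideal alpha helix: 100 deg/residue, 1.5 Å rise; radius fixed by the
# 3.8 Å virtual CA-CA bond.
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RISE = 1.5
HELIX_RADIUS = float(np.sqrt(geometry.BOND_CA_CA ** 2 - HELIX_RISE ** 2)
                     / (2.0 * np.sin(HELIX_TWIST / 2.0)))

# Ideal antiparallel strand: 3.3 Å step along the strand axis, pleat
# amplitude fixed by the CA-CA bond; 4.8 Å between paired strands.
STRAND_STEP = 3.3
STRAND_PLEAT = float(np.sqrt(geometry.BOND_CA_CA ** 2 - STRAND_STEP ** 2) / 2.0)
STRAND_SPACING = 4.8

#: Default toy switch sequence: hydrophobic positions roughly compatible
#: with both a packed helix face and a strand core.
_TOY_SEQ = "LKEILSEAVKDLTKEIASNVLGEKILSDAVTKEILSNAVKELTSDIVKGLASE"


def default_switch_sequence(n: int) -> str:
    if n > len(_TOY_SEQ):
        reps = -(-n // len(_TOY_SEQ))
        return (_TOY_SEQ * reps)[:n]
    return _TOY_SEQ[:n]


def design_switch_sequence(n: int, turn_len: int = 5,
                           packing_distance: float = 9.0) -> str:
    """Sequence designed for the alpha-hairpin state.

    Hydrophobic residues (L/I/V) go where the CB points at the partner
    helix in the hairpin geometry, the turn gets small polar residues, and
    everything else cycles through charged/polar types — so the designed
    helix-helix interface is the contact-energy optimum of the fold rather
    than an accident of the pattern.
    """
    template = build_alpha_hairpin(n, "A" * n, turn_len=turn_len,
                                   packing_distance=packing_distance)
    h_len, rem = divmod(n - turn_len, 2)
    h1 = h_len + rem
    hyd, pol, turn = "LIVLIV", "EKSEKQ", "GNSGQ"
    ih = ip = 0
    seq = []
    for i in range(n):
        if h1 <= i < h1 + turn_len:
            seq.append(turn[(i - h1) % len(turn)])
            continue
        cb = template.cb_xyz[i] - template.ca_xyz[i]
        cb /= np.linalg.norm(cb)
        facing = cb[0] if i < h1 else -cb[0]
        if facing > 0.3:
            seq.append(hyd[ih % len(hyd)])
            ih += 1
        else:
            seq.append(pol[ip % len(pol)])
            ip += 1
    return "".join(seq)


def _finish_chain(ca: np.ndarray, sequence: str,
                  domain_label: list[str] | None = None) -> CoarseChain:
    """Attach ideal CB/O beads to a CA trace and validate."""
    ca = np.asarray(ca, float)
    chain = CoarseChain(sequence=sequence, ca_xyz=ca,
                        cb_xyz=geometry.place_virtual_cb(ca),
                        o_xyz=geometry.place_virtual_o(ca),
                        domain_label=domain_label or [])
    chain.validate()
    return chain


def helix_ca_trace(n: int, start: np.ndarray | None = None,
                   axis_z: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """CA trace of an ideal alpha helix along +-z."""
    i = np.arange(n)
    ca = np.stack([HELIX_RADIUS * np.cos(phase + i * HELIX_TWIST),
                   HELIX_RADIUS * np.sin(phase + i * HELIX_TWIST),
                   axis_z * HELIX_RISE * i], axis=1)
    if start is not None:
        ca = ca - ca[0] + np.asarray(start, float)
    return ca


def build_ideal_helix(n: int, sequence: str | None = None) -> CoarseChain:
    """Canonical alpha helix (rise 1.5 Å/residue, ~3.6 residues/turn)."""
    if n < 4:
        raise StructureError("helix needs at least 4 residues")
    sequence = sequence or default_switch_sequence(n)
    if len(sequence) != n:
        raise StructureError("sequence length mismatch")
    return _finish_chain(helix_ca_trace(n), sequence)


def _arc_connect(p_start: np.ndarray, p_end: np.ndarray, k: int,
                 bulge_dir: np.ndarray) -> np.ndarray:
    """Place k intermediate residues between two anchors on a circular arc.

    The arc lies in the plane spanned by the end-to-end chord and
    ``bulge_dir`` and its radius/angle are solved so that all k+1 segments
    equal the ideal 3.8 Å CA-CA bond (exactly, whenever the chord is short
    enough; otherwise bonds are uniformly stretched along the chord).
    """
    p_start, p_end = np.asarray(p_start, float), np.asarray(p_end, float)
    m = k + 1  # number of segments
    chord_vec = p_end - p_start
    c = float(np.linalg.norm(chord_vec))
    w = np.asarray(bulge_dir, float)
    w = w - w.dot(chord_vec) * chord_vec / max(c * c, 1e-12)
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        w = np.cross(chord_vec, [0.27, 0.62, 0.73])
        nw = np.linalg.norm(w)
    w = w / nw
    bond = geometry.BOND_CA_CA
    if c >= m * bond:  # cannot reach with ideal bonds: straight, stretched
        t = np.arange(1, k + 1) / m
        return p_start + t[:, None] * chord_vec

    # total arc angle phi solving  c = bond * sin(phi/2) / sin(phi/(2m))
    def resid(phi: float) -> float:
        return bond * np.sin(phi / 2.0) / np.sin(phi / (2.0 * m)) - c

    phi = brentq(resid, 1e-6, 2.0 * np.pi - 1e-6)
    radius = bond / (2.0 * np.sin(phi / (2.0 * m)))
    u = chord_vec / max(c, 1e-12)
    # circle center sits off the chord midpoint along -w
    sagitta = radius * np.cos(phi / 2.0)
    center = 0.5 * (p_start + p_end) - sagitta * w
    angles = -phi / 2.0 + phi * np.arange(1, k + 1) / m
    return (center[None, :]
            + radius * np.cos(angles)[:, None] * w[None, :]
            + radius * np.sin(angles)[:, None] * u[None, :])


def meander_ca_trace(n_strands: int, strand_len: int, turn_len: int) -> np.ndarray:
    """CA trace of an antiparallel beta meander in the xy plane."""
    traces = []
    for s in range(n_strands):
        i = np.arange(strand_len)
        x = i * STRAND_STEP if s % 2 == 0 else (strand_len - 1 - i) * STRAND_STEP
        y = np.full(strand_len, s * STRAND_SPACING)
        z = STRAND_PLEAT * (-1.0) ** (i + s)
        traces.append(np.stack([x, y, z], axis=1))
    ca = [traces[0]]
    for s in range(1, n_strands):
        p_start, p_end = ca[-1][-1], traces[s][0]
        bulge = np.array([1.0, 0.0, 0.0])
        if p_end[0] < STRAND_STEP:  # turn at the x=0 end: bulge outwards
            bulge = np.array([-1.0, 0.0, 0.0])
        ca.append(_arc_connect(p_start, p_end, turn_len, bulge))
        ca.append(traces[s])
    return np.vstack(ca)


def build_beta_meander(n: int, n_strands: int = 3,
                       sequence: str | None = None,
                       turn_len: int = 3) -> CoarseChain:
    """Antiparallel meander with >= 3-residue strands and ~4.8 Å ladders."""
    if not 2 <= n_strands <= 4:
        raise StructureError("n_strands must be in 2..4")
    strand_len, rem = divmod(n - (n_strands - 1) * turn_len, n_strands)
    if rem or strand_len < 3:
        raise StructureError(
            f"cannot tile {n} residues into {n_strands} equal strands "
            f"(>= 3 residues each) with {turn_len}-residue turns")
    sequence = sequence or default_switch_sequence(n)
    if len(sequence) != n:
        raise StructureError("sequence length mismatch")
    return _finish_chain(meander_ca_trace(n_strands, strand_len, turn_len),
                         sequence)


def build_alpha_hairpin(n: int, sequence: str | None = None,
                        turn_len: int = 5,
                        packing_distance: float = 9.0) -> CoarseChain:
    """Two antiparallel packed helices joined by a short turn."""
    h_len, rem = divmod(n - turn_len, 2)
    if h_len < 4:
        raise StructureError(f"{n} residues too few for an alpha hairpin")
    h1_len, h2_len = h_len + rem, h_len
    sequence = sequence or default_switch_sequence(n)
    if len(sequence) != n:
        raise StructureError("sequence length mismatch")
    h1 = helix_ca_trace(h1_len, axis_z=1.0)
    top_z = h1[-1, 2]
    # helix 2 runs antiparallel, its start near the top of helix 1 but offset
    # by the packing distance
    h2 = helix_ca_trace(h2_len, axis_z=-1.0, phase=np.pi)
    h2 = h2 - h2[0] + np.array([packing_distance, 0.0, top_z])
    turn = _arc_connect(h1[-1], h2[0], turn_len, np.array([0.4, 0.9, 0.6]))
    return _finish_chain(np.vstack([h1, turn, h2]), sequence)


@dataclass
class ToyFoldSwitchPair:
    """One sequence with two reference folds (A: alpha hairpin, B: meander)."""

    sequence: str
    state_a: CoarseChain
    state_b: CoarseChain
    ref_a: ReferenceState
    ref_b: ReferenceState
    switch_range: tuple[int, int] = (1, 0)  # 1-based inclusive, set in factory
    anchor_range: tuple[int, int] | None = None
    linker_range: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)


def _rigid_place(ca: np.ndarray, shift: np.ndarray,
                 rot: np.ndarray | None = None) -> np.ndarray:
    out = ca - ca.mean(axis=0)
    if rot is not None:
        out = out @ rot.T
    return out + shift


def make_toy_foldswitch_pair(n_switch: int = 33, with_anchor: bool = False,
                             anchor_len: int = 16, linker_len: int = 10,
                             sequence: str | None = None,
                             seed: int = 0) -> ToyFoldSwitchPair:
    """Build the paired two-fold toy protein.

    Without an anchor the two states are the bare hairpin/meander and the
    references carry no mask.  With an anchor, state A docks the hairpin
    against the anchor (interdomain contacts present in the A matrix) while
    state B keeps the meander dissociated; following the exclusion scheme
    used for a rigid non-switching domain, anchor-internal pairs are masked
    in both matrices and anchor-to-rest pairs are additionally masked in B.
    """
    del seed  # geometry is deterministic; kept for interface stability
    seq_switch = sequence or design_switch_sequence(n_switch)
    if len(seq_switch) != n_switch:
        raise StructureError("sequence length mismatch")
    hairpin = build_alpha_hairpin(n_switch, seq_switch)
    meander = build_beta_meander(n_switch, 3, seq_switch)

    if not with_anchor:
        dm_a = build_distance_matrix(hairpin)
        dm_b = build_distance_matrix(meander)
        rms_diff = float(np.sqrt(np.mean((dm_a.d - dm_b.d) ** 2)))
        pair = ToyFoldSwitchPair(
            sequence=seq_switch, state_a=hairpin, state_b=meander,
            ref_a=ReferenceState("toyA_hairpin", hairpin, dm_a, "synthetic"),
            ref_b=ReferenceState("toyB_meander", meander, dm_b, "synthetic"),
            switch_range=(1, n_switch),
            meta={"dmatrix_rms_difference": rms_diff})
        return pair

    anchor_seq = default_switch_sequence(anchor_len + linker_len + n_switch)
    seq_full = anchor_seq[:anchor_len] + "GSGNGSGTGS"[:linker_len] + seq_switch
    anchor = build_alpha_hairpin(anchor_len, seq_full[:anchor_len], turn_len=4)

    def fuse(switch: CoarseChain, dock_shift: np.ndarray) -> CoarseChain:
        a_ca = anchor.ca_xyz - anchor.ca_xyz.mean(axis=0)
        s_ca = _rigid_place(switch.ca_xyz, dock_shift)
        linker = _arc_connect(a_ca[-1], s_ca[0], linker_len,
                              np.array([0.2, 1.0, 0.3]))
        ca = np.vstack([a_ca, linker, s_ca])
        labels = (["anchor"] * anchor_len + ["linker"] * linker_len
                  + ["switch"] * switch.n_residues)
        return _finish_chain(ca, seq_full, labels)

    # state A: hairpin docked against the anchor (cross contacts <= 9.5 Å)
    state_a = fuse(hairpin, np.array([11.0, 2.0, 0.0]))
    # state B: meander dissociated from the anchor
    state_b = fuse(meander, np.array([34.0, 6.0, 0.0]))

    n_total = anchor_len + linker_len + n_switch
    a_rng = (1, anchor_len)
    all_rng = (1, n_total)
    dm_a = apply_exclusions(build_distance_matrix(state_a), [(a_rng, a_rng)])
    dm_b = apply_exclusions(build_distance_matrix(state_b),
                            [(a_rng, a_rng), (a_rng, all_rng)])
    return ToyFoldSwitchPair(
        sequence=seq_full, state_a=state_a, state_b=state_b,
        ref_a=ReferenceState("toyA_anchored", state_a, dm_a, "synthetic"),
        ref_b=ReferenceState("toyB_dissociated", state_b, dm_b, "synthetic"),
        switch_range=(anchor_len + linker_len + 1, n_total),
        anchor_range=a_rng,
        linker_range=(anchor_len + 1, anchor_len + linker_len))


def sample_random_coil(sequence: str, seed: int,
                       reference: ReferenceState | None = None,
                       qw_threshold: float = 0.1,
                       max_retries: int = 200) -> CoarseChain:
    """Self-avoiding random CA walk with ideal CB/O beads.

    Bond lengths are 3.8 Å, pseudo-angles drawn from a broad coil range and
    no non-adjacent CA pair comes below 3.0 Å.  If a reference is supplied,
    candidates are regenerated until Q_W(all_pairs) < ``qw_threshold``;
    attempts alternate between extended- and compact-biased angle ranges so
    a sufficiently dissimilar coil exists whatever the reference topology
    (short chains have a nonzero Q_W floor from near-diagonal pairs, so
    unbiased coils often sit just above 0.1).
    """
    from . import cv as _cv

    n = len(sequence)
    rng = np.random.default_rng(seed)
    angle_families = ((100.0, 150.0), (75.0, 115.0), (75.0, 140.0))
    for attempt in range(max_retries):
        lo, hi = angle_families[attempt % len(angle_families)]
        ca = _random_walk(n, rng, angle_lo=lo, angle_hi=hi)
        if ca is None:
            continue
        chain = _finish_chain(ca, sequence)
        if reference is not None and \
                _cv.compute_qw(chain, reference, "all_pairs") >= qw_threshold:
            continue
        return chain
    raise StructureError(
        f"could not generate an acceptable random coil in {max_retries} tries")


def _random_walk(n: int, rng: np.random.Generator,
                 min_sep: float = 3.0, angle_lo: float = 75.0,
                 angle_hi: float = 140.0) -> np.ndarray | None:
    ca = np.zeros((n, 3))
    ca[1] = [geometry.BOND_CA_CA, 0.0, 0.0]
    for i in range(2, n):
        placed = False
        for _ in range(60):
            theta = np.deg2rad(rng.uniform(angle_lo, angle_hi))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            prev = ca[i - 1] - ca[i - 2]
            prev /= np.linalg.norm(prev)
            # random unit vector at angle (pi - theta) from prev
            perp = np.cross(prev, rng.standard_normal(3))
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(prev, perp)
            direction = (np.cos(np.pi - theta) * prev
                         + np.sin(np.pi - theta) * (np.cos(phi) * perp
                                                    + np.sin(phi) * perp2))
            cand = ca[i - 1] + geometry.BOND_CA_CA * direction
            if i >= 2 and np.min(np.linalg.norm(ca[:i - 1] - cand, axis=1)) < min_sep:
                continue
            ca[i] = cand
            placed = True
            break
        if not placed:
            return None
    return ca
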