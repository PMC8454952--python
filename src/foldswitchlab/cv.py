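"""Collective variables for fold-switching.

Two order parameters drive and report on the simulations:

* ``Q_diff`` — a dual-reference progress coordinate.  A Gaussian-weighted
  similarity ``q`` is computed over the union of contacts present in either
  reference fold (CA-CA distance <= 9.5 Å, sequence separation > 2) and
  affinely renormalized so that reference A maps to 0 and reference B to 1.
  Pair widths grow slowly with sequence separation, sigma_ij = |j-i|^0.15 Å.
* ``Q_W`` — a single-reference similarity.  In the ``all_pairs`` variant the
  sum runs over every pair with j > i+2 and native self-similarity is exactly
  1; the ``contact_restricted`` variant sums only native contacts
  (< 9.5 Å), keeping the same 2/((N-2)(N-3)) normalization, and therefore
  saturates well below 1 for typical proteins.  Both variants are computed
  explicitly; nothing silently assumes one convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import CoarseChain, DistanceMatrix, ReferenceState, StructureError
from .geometry import rmsd_after_superposition

#: Native-contact CA-CA cutoff (Å), inclusive for the union contact set.
CONTACT_CUTOFF = 9.5
#: Exponent of the sequence-separation-dependent pair width sigma_ij (Å).
SIGMA_EXPONENT = 0.15
#: Minimum sequence separation: pairs require j > i + 2.
MIN_SEPARATION = 3


def pair_sigma(separation: np.ndarray) -> np.ndarray:
    """sigma_ij = |j - i|^0.15 in Å."""
    return np.abs(separation).astype(float) ** SIGMA_EXPONENT


@dataclass
class ContactPairSet:
    """Union contact set of two reference folds (0-based indices, j > i+2)."""

    i: np.ndarray
    j: np.ndarray
    in_a: np.ndarray
    in_b: np.ndarray
    r_a: np.ndarray  # reference-A CA distance, Å (sentinel where masked)
    r_b: np.ndarray
    sigma: np.ndarray
    n_residues: int

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class QdiffSpec:
    """Everything needed to evaluate Q_diff: contact set + endpoint constants."""

    contact_set: ContactPairSet
    q_a: float
    q_b: float
    name_a: str = "A"
    name_b: str = "B"

    def __post_init__(self) -> None:
        if abs(self.q_a - self.q_b) < 1e-12:
            raise ValueError("degenerate spec: q_A equals q_B")


def build_contact_set(ref_a: ReferenceState, ref_b: ReferenceState,
                      cutoff: float = CONTACT_CUTOFF) -> ContactPairSet:
    """Union contact set: pairs <= cutoff in at least one reference.

    Masked matrix entries never qualify as contacts; for pairs that do
    qualify, the stored per-reference distances are the *materialized* ones
    (masked entries appear as the 99 Å sentinel), so that both Gaussian
    terms of the q function are always evaluated, as in the literal formula.
    """
    n = ref_a.dmatrix.n
    if ref_b.dmatrix.n != n:
        raise StructureError(
            f"references differ in length: {n} vs {ref_b.dmatrix.n}")
    da, db = ref_a.dmatrix.materialized(), ref_b.dmatrix.materialized()
    ii, jj = np.triu_indices(n, k=MIN_SEPARATION)
    qual_a = (da[ii, jj] <= cutoff) & ~ref_a.dmatrix.mask[ii, jj]
    qual_b = (db[ii, jj] <= cutoff) & ~ref_b.dmatrix.mask[ii, jj]
    keep = qual_a | qual_b
    if not np.any(keep):
        raise StructureError("no contacts qualify in either reference "
                             "(all entries masked or beyond cutoff)")
    ii, jj = ii[keep], jj[keep]
    return ContactPairSet(
        i=ii, j=jj, in_a=qual_a[keep], in_b=qual_b[keep],
        r_a=da[ii, jj], r_b=db[ii, jj], sigma=pair_sigma(jj - ii),
        n_residues=n)


def _pair_distances(chain: CoarseChain, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    ca = chain.ca_xyz
    return np.linalg.norm(ca[i] - ca[j], axis=1)


def compute_q(chain: CoarseChain, spec: QdiffSpec | ContactPairSet) -> float:
    """The dual-reference q function over the union contact set.

    q = 1/((N-2)(N-3)) * sum over pairs of
    [exp(-(r-r^A)^2 / 2 sigma^2) + 1 - exp(-(r-r^B)^2 / 2 sigma^2)].
    """
    cs = spec.contact_set if isinstance(spec, QdiffSpec) else spec
    if chain.n_residues != cs.n_residues:
        raise StructureError(
            f"chain length {chain.n_residues} != reference length {cs.n_residues}")
    r = _pair_distances(chain, cs.i, cs.j)
    two_s2 = 2.0 * cs.sigma ** 2
    term = (np.exp(-(r - cs.r_a) ** 2 / two_s2)
            + 1.0 - np.exp(-(r - cs.r_b) ** 2 / two_s2))
    n = cs.n_residues
    return float(term.sum() / ((n - 2) * (n - 3)))


def make_qdiff_spec(ref_a: ReferenceState, ref_b: ReferenceState,
                    cutoff: float = CONTACT_CUTOFF) -> QdiffSpec:
    """Build the Q_diff specification with endpoint constants q_A, q_B.

    Orientation: ``ref_a`` maps to Q_diff = 0, ``ref_b`` to Q_diff = 1.
    """
    cs = build_contact_set(ref_a, ref_b, cutoff)
    q_a = compute_q(ref_a.chain, cs)
    q_b = compute_q(ref_b.chain, cs)
    if abs(q_a - q_b) < 1e-12:
        raise StructureError("references indistinguishable: q_A == q_B")
    return QdiffSpec(contact_set=cs, q_a=q_a, q_b=q_b,
                     name_a=ref_a.name, name_b=ref_b.name)


def compute_qdiff(chain: CoarseChain, spec: QdiffSpec) -> float:
    """Q_diff = (q - q_A) / (q_B - q_A); not clamped to [0, 1]."""
    return (compute_q(chain, spec) - spec.q_a) / (spec.q_b - spec.q_a)


def compute_qw(chain: CoarseChain, ref: ReferenceState | DistanceMatrix,
               variant: str = "all_pairs",
               cutoff: float = CONTACT_CUTOFF) -> float:
    """Single-reference similarity Q_W.

    ``all_pairs``: sum over every j > i+2 pair (native self-similarity = 1).
    ``contact_restricted``: sum only over native contacts with reference
    distance strictly < cutoff; masked pairs never qualify.  Both use the
    2/((N-2)(N-3)) normalization.
    """
    dm = ref.dmatrix if isinstance(ref, ReferenceState) else ref
    n = dm.n
    if chain.n_residues != n:
        raise StructureError(
            f"chain length {chain.n_residues} != reference length {n}")
    ii, jj = np.triu_indices(n, k=MIN_SEPARATION)
    r_ref = dm.d[ii, jj]
    if variant == "all_pairs":
        keep = np.ones(len(ii), bool)
    elif variant == "contact_restricted":
        keep = (r_ref < cutoff) & ~dm.mask[ii, jj]
    else:
        raise ValueError(f"unknown Q_W variant {variant!r}")
    ii, jj, r_ref = ii[keep], jj[keep], r_ref[keep]
    r = _pair_distances(chain, ii, jj)
    sig = pair_sigma(jj - ii)
    g = np.exp(-(r - r_ref) ** 2 / (2.0 * sig ** 2))
    return float(2.0 * g.sum() / ((n - 2) * (n - 3)))


def best_fit_rmsd(chain: CoarseChain, ref: ReferenceState | CoarseChain,
                  selection: tuple[int, int] | None = None) -> float:
    """CA RMSD after optimal rigid superposition (Kabsch).

    ``selection`` is a 1-based inclusive residue range applied to both.
    """
    other = ref.chain if isinstance(ref, ReferenceState) else ref
    a, b = chain.ca_xyz, other.ca_xyz
    if selection is not None:
        lo, hi = selection
        if lo < 1 or hi > min(len(a), len(b)) or lo > hi:
            raise StructureError(f"bad selection {selection}")
        a, b = a[lo - 1:hi], b[lo - 1:hi]
    if len(a) != len(b):
        raise StructureError("selection lengths differ between structures")
    if len(a) == 0:
        raise StructureError("empty selection")
    return rmsd_after_superposition(a, b)
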